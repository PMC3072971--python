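"""Aligned nucleotide matrices: I/O, site classification, concatenation, K2P.

This module supports the molecular side of the analysis: classifying
alignment columns as constant / variable-but-parsimony-uninformative /
parsimony-informative, building a concatenated supermatrix across marker
partitions (merging specimens of the same species sequenced for different
markers), and Kimura 2-parameter distances.

Conventions: gaps (``-``), ``?`` and IUPAC ambiguity codes are missing data
in every statistic (they are preserved in I/O); K2P uses pairwise deletion
of sites where either sequence is not a plain A/C/G/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "AlignmentError",
    "SaturationError",
    "AlignedSequenceMatrix",
    "SiteClassification",
    "read_alignment",
    "classify_sites",
    "concatenate",
    "k2p_distance",
    "between_group_k2p",
]

_NUCS = frozenset("ACGT")
_AMBIG = frozenset("RYSWKMBDHVN")
_MISSING = frozenset("-?") | _AMBIG
_VALID = _NUCS | _MISSING

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class AlignmentError(ValueError):
    """Ragged alignments, unknown symbols, or invalid concatenation input."""


class SaturationError(ValueError):
    """K2P log argument non-positive: divergence beyond the correctable range."""


class AlignedSequenceMatrix:
    """Rectangular taxa x sites nucleotide matrix with a partition name."""

    def __init__(self, taxa: Sequence[str], sequences: Sequence[str], name: str = ""):
        taxa = list(taxa)
        seqs = [s.upper() for s in sequences]
        if len(taxa) != len(seqs):
            raise AlignmentError("taxa and sequences differ in count")
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxa in alignment")
        if not seqs or len(seqs[0]) < 1:
            raise AlignmentError("alignment must have width >= 1")
        width = len(seqs[0])
        for t, s in zip(taxa, seqs):
            if len(s) != width:
                raise AlignmentError(
                    f"ragged alignment: taxon {t!r} has length {len(s)}, expected {width}"
                )
            bad = set(s) - _VALID
            if bad:
                raise AlignmentError(f"unknown symbol(s) {sorted(bad)} in taxon {t!r}")
        self.taxa = taxa
        self.name = name
        self._rows = dict(zip(taxa, seqs))
        self.array = np.array([list(s) for s in seqs], dtype="U1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def width(self) -> int:
        return self.array.shape[1]

    def sequence(self, taxon: str) -> str:
        return self._rows[taxon]

    def column(self, j: int) -> list[str]:
        return list(self.array[:, j])

    # -- I/O ----------------------------------------------------------

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self._rows[t]}\n")

    def write_nexus(self, path, charsets: Mapping[str, tuple[int, int]] | None = None) -> None:
        """NEXUS data block; optional 1-based inclusive charset ranges as a sets block."""
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.width};",
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "  MATRIX",
        ]
        for t in self.taxa:
            lines.append(f"    {t.replace(' ', '_')}  {self._rows[t]}")
        lines += ["  ;", "END;"]
        if charsets:
            lines.append("BEGIN SETS;")
            for nm, (a, b) in charsets.items():
                lines.append(f"  CHARSET {nm} = {a}-{b};")
            lines.append("END;")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_alignment(path, format: str | None = None, name: str | None = None) -> AlignedSequenceMatrix:
    """Read a FASTA or NEXUS alignment (format inferred from suffix if omitted)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "nexus" if suffix in {".nex", ".nexus"} else "fasta"
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif format == "nexus":
        aln = AlignIO.read(str(path), "nexus")
        taxa = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    else:
        raise AlignmentError(f"unsupported format: {format}")
    return AlignedSequenceMatrix(taxa, seqs, name=name or path.stem)


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------


@dataclass
class SiteClassification:
    """Per-site labels and summary counts (constant / uninformative / informative)."""

    labels: list[str]

    @property
    def counts(self) -> dict[str, int]:
        out = {"constant": 0, "variable-uninformative": 0, "parsimony-informative": 0}
        for lb in self.labels:
            out[lb] += 1
        return out

    @property
    def n_constant(self) -> int:
        return self.counts["constant"]

    @property
    def n_uninformative(self) -> int:
        return self.counts["variable-uninformative"]

    @property
    def n_informative(self) -> int:
        return self.counts["parsimony-informative"]

    def to_tsv(self, path_or_buf=None) -> str | None:
        import pandas as pd

        df = pd.DataFrame({"site": range(1, len(self.labels) + 1), "label": self.labels})
        return df.to_csv(path_or_buf, sep="\t", index=False)


def classify_sites(m: AlignedSequenceMatrix) -> SiteClassification:
    """Classify each column as constant, variable-uninformative, or parsimony-informative.

    A column is parsimony-informative when at least two distinct unambiguous
    nucleotides each occur in at least two taxa; constant when at most one
    distinct unambiguous nucleotide occurs; variable-uninformative
    otherwise.  Gaps, ``?`` and ambiguity codes never count.
    """
    if m.n_taxa < 2:
        raise AlignmentError("site classification needs >= 2 taxa")
    labels = []
    for j in range(m.width):
        col = m.array[:, j]
        counts: dict[str, int] = {}
        for sym in col:
            if sym in _NUCS:
                counts[sym] = counts.get(sym, 0) + 1
        distinct = len(counts)
        if distinct <= 1:
            labels.append("constant")
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            labels.append("parsimony-informative")
        else:
            labels.append("variable-uninformative")
    return SiteClassification(labels)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def concatenate(
    partitions: Sequence[AlignedSequenceMatrix],
    merge_key: Mapping[str, str] | None = None,
    missing_symbol: str = "?",
) -> AlignedSequenceMatrix:
    """Concatenate marker partitions into one supermatrix.

    ``merge_key`` maps specimen labels to species labels, so markers
    sequenced from different specimens of the same species end up on one
    row.  A species absent from a partition is filled with
    ``missing_symbol`` across that partition's span.  Two specimens of the
    same species within a single partition are an error (the caller must
    pre-select one).  Partition boundaries (1-based, inclusive) are stored
    on the result as ``.charsets``.
    """
    if not partitions:
        raise AlignmentError("no partitions to concatenate")
    key = dict(merge_key or {})

    def species_of(label: str) -> str:
        return key.get(label, label)

    species_order: list[str] = []
    seen = set()
    for part in partitions:
        for t in part.taxa:
            sp = species_of(t)
            if sp not in seen:
                seen.add(sp)
                species_order.append(sp)

    per_part_rows = []
    for part in partitions:
        rows: dict[str, str] = {}
        for t in part.taxa:
            sp = species_of(t)
            if sp in rows:
                raise AlignmentError(
                    f"partition {part.name!r}: two specimens map to species {sp!r}"
                )
            rows[sp] = part.sequence(t)
        per_part_rows.append(rows)

    seqs = []
    for sp in species_order:
        chunks = [
            rows.get(sp, missing_symbol * part.width)
            for part, rows in zip(partitions, per_part_rows)
        ]
        seqs.append("".join(chunks))

    out = AlignedSequenceMatrix(species_order, seqs, name="concatenated")
    charsets: dict[str, tuple[int, int]] = {}
    start = 1
    for i, part in enumerate(partitions):
        nm = part.name or f"partition{i + 1}"
        charsets[nm] = (start, start + part.width - 1)
        start += part.width
    out.charsets = charsets
    return out


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def k2p_distance(s1: str, s2: str) -> float:
    """Kimura 2-parameter distance in substitutions/site, pairwise deletion.

    With transition proportion P and transversion proportion Q over the
    retained sites, ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``.
    """
    s1, s2 = s1.upper(), s2.upper()
    if len(s1) != len(s2):
        raise AlignmentError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in _NUCS or b not in _NUCS:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise AlignmentError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: saturated divergence (P={P:.4g}, Q={Q:.4g})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def between_group_k2p(
    m: AlignedSequenceMatrix, group1: Sequence[str], group2: Sequence[str]
) -> float:
    """Arithmetic mean K2P over all cross-group sequence pairs."""
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise AlignmentError("both groups must be non-empty")
    ds = [k2p_distance(m.sequence(a), m.sequence(b)) for a in g1 for b in g2]
    return float(np.mean(ds))
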