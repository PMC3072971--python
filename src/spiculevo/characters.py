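"""Discrete character matrices and taxon depth metadata.

The morphological data are binary presence/absence characters (spicule
types) scored over the tree's tips, with ``?`` allowed for missing scores.
Characters carry a class label — ``megasclere`` (large structural spicules)
or ``microsclere`` (small spicules) — used when homoplasy counts are
aggregated.  Depth metadata records each species' bathymetric habit
(``shallow``, ``deep``, or ``both`` for species recorded on both sides of
the depth threshold, 100 m by default).

File formats
------------
Character matrices read/write a TSV whose first column is the taxon and
whose remaining headers are ``name`` or ``name|class``, and a NEXUS
characters block (states 0/1/?, via dendropy).  Depth metadata is TSV with
columns ``taxon`` and ``habit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

__all__ = ["CharacterColumn", "CharacterMatrix", "DepthMetadata"]

MISSING = -1  # internal code for '?'

_VALID_HABITS = ("shallow", "deep", "both")


@dataclass(frozen=True)
class CharacterColumn:
    """One discrete character scored over taxa.

    ``states`` maps taxon label to an integer state in ``0..k-1`` or
    :data:`MISSING` for an unscored taxon.
    """

    name: str
    states: Mapping[str, int]
    char_class: str | None = None

    def state_of(self, taxon: str) -> int:
        return self.states[taxon]

    def observed(self) -> dict[str, int]:
        return {t: s for t, s in self.states.items() if s != MISSING}

    def n_observed_states(self) -> int:
        return len(set(self.observed().values()))


class CharacterMatrix:
    """Taxa x characters matrix of small integer states with missing data."""

    def __init__(self, df: pd.DataFrame, classes: Mapping[str, str] | None = None):
        if df.index.has_duplicates:
            raise ValueError("duplicate taxa in character matrix")
        self.df = df.astype(int)
        self.classes = dict(classes or {})

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def character_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_characters(self) -> int:
        return self.df.shape[1]

    def column(self, name: str) -> CharacterColumn:
        return CharacterColumn(
            name=name,
            states=self.df[name].to_dict(),
            char_class=self.classes.get(name),
        )

    def columns(self) -> list[CharacterColumn]:
        return [self.column(c) for c in self.df.columns]

    # -- I/O ----------------------------------------------------------

    @classmethod
    def from_columns(cls, columns: list[CharacterColumn]) -> "CharacterMatrix":
        df = pd.DataFrame({c.name: pd.Series(c.states) for c in columns})
        classes = {c.name: c.char_class for c in columns if c.char_class}
        return cls(df, classes)

    @classmethod
    def read_tsv(cls, path_or_buf) -> "CharacterMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
        taxon_col = df.columns[0]
        df = df.set_index(taxon_col)
        classes = {}
        renames = {}
        for col in df.columns:
            if "|" in col:
                name, klass = col.split("|", 1)
                renames[col] = name
                classes[name] = klass
        df = df.rename(columns=renames)
        df = df.replace("?", str(MISSING))
        return cls(df.astype(int), classes)

    def to_tsv(self, path_or_buf=None) -> str | None:
        out = self.df.copy()
        out.columns = [
            f"{c}|{self.classes[c]}" if c in self.classes else c for c in out.columns
        ]
        out = out.astype(str).replace(str(MISSING), "?")
        out.index.name = "taxon"
        return out.to_csv(path_or_buf, sep="\t")

    @classmethod
    def read_nexus(cls, path) -> "CharacterMatrix":
        mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        rows = {}
        for taxon in mat:
            seq = mat[taxon]
            states = []
            for cell in seq:
                sym = str(cell)
                states.append(MISSING if sym in "?-" else int(sym))
            rows[taxon.label] = states
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [f"char{i + 1}" for i in range(df.shape[1])]
        return cls(df)

    def to_nexus(self, path_or_buf=None) -> str | None:
        k = int(max(2, self.df.replace(MISSING, 0).to_numpy().max() + 1))
        symbols = "".join(str(i) for i in range(k))
        lines = [
            "#NEXUS",
            "BEGIN CHARACTERS;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};",
            f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;',
            "  MATRIX",
        ]
        for taxon in self.taxa:
            row = "".join(
                "?" if s == MISSING else str(s) for s in self.df.loc[taxon]
            )
            safe = taxon.replace(" ", "_")
            lines.append(f"    {safe}  {row}")
        lines += ["  ;", "END;", ""]
        text = "\n".join(lines)
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)
        return None


@dataclass
class DepthMetadata:
    """Bathymetric habit per taxon, relative to a depth threshold in meters."""

    habits: dict[str, str]
    depth_threshold_m: float = 100.0

    def __post_init__(self):
        bad = {t: h for t, h in self.habits.items() if h not in _VALID_HABITS}
        if bad:
            raise ValueError(f"invalid habit values: {bad}")

    def habit(self, taxon: str) -> str:
        return self.habits[taxon]

    def validate_tips(self, tip_labels) -> None:
        missing = [t for t in tip_labels if t not in self.habits]
        if missing:
            raise ValueError(f"no depth metadata for tips: {missing}")

    def counts(self) -> dict[str, int]:
        out = {h: 0 for h in _VALID_HABITS}
        for h in self.habits.values():
            out[h] += 1
        return out

    @classmethod
    def read_tsv(cls, path_or_buf, depth_threshold_m: float = 100.0) -> "DepthMetadata":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
        return cls(dict(zip(df["taxon"], df["habit"])), depth_threshold_m)

    def to_tsv(self, path_or_buf=None) -> str | None:
        df = pd.DataFrame(
            {"taxon": list(self.habits), "habit": list(self.habits.values())}
        )
        return df.to_csv(path_or_buf, sep="\t", index=False)
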