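"""Readers, writers, and validated domain types for the lexical pipeline.

The data model mirrors the long/tidy layout used by comparative wordlist
databases: one row per (variety, concept, form), with an optional
cognate-class column.  Distance matrices travel as square, labeled,
tab-separated text; trait tables (one bounded value per group/province)
as two-column CSV or TSV.
"""

from __future__ import annotations

import logging
import unicodedata
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix, DistanceMatrixError

logger = logging.getLogger("galtonlex")

#: variety_id -> group (province) id
GroupMap = dict[str, str]

#: symmetric-read tolerance for matrix files
ASYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """A file does not conform to its declared layout."""


class ValidationError(ValueError):
    """File parsed, but its content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Wordlists
# ---------------------------------------------------------------------------

class Wordlist:
    """One variety's concept -> word-form mapping, with optional cognacy.

    Parameters
    ----------
    variety_id : str
        Identifier of the language variety.
    entries : mapping
        ``concept_id -> iterable of (form, cognate_class)`` where
        ``cognate_class`` may be None.  Cognate coding must be present for
        all forms or for none; mixed coding is rejected.  Forms are
        NFC-normalized; per-concept form lists are stored sorted so equal
        content compares equal regardless of input row order.
    """

    __slots__ = ("variety_id", "entries")

    def __init__(
        self,
        variety_id: str,
        entries: Mapping[str, Iterable[tuple[str, str | None]]],
    ) -> None:
        if not variety_id:
            raise ValidationError("variety_id must be a non-empty string")
        if not entries:
            raise ValidationError(f"wordlist {variety_id!r} has no concepts")
        norm: dict[str, tuple[tuple[str, str | None], ...]] = {}
        coding: set[bool] = set()
        for concept, forms in entries.items():
            pairs = []
            for form, cog in forms:
                if not form:
                    raise ValidationError(
                        f"empty form for concept {concept!r} in variety {variety_id!r}"
                    )
                coding.add(cog is not None)
                pairs.append((unicodedata.normalize("NFC", form), cog))
            if not pairs:
                raise ValidationError(
                    f"concept {concept!r} of variety {variety_id!r} has no forms"
                )
            norm[concept] = tuple(sorted(pairs, key=lambda p: (p[0], p[1] or "")))
        if len(coding) > 1:
            raise ValidationError(
                f"variety {variety_id!r} mixes cognate-coded and uncoded forms"
            )
        self.variety_id = variety_id
        self.entries = norm

    # -- accessors ---------------------------------------------------------

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(self.entries)

    @property
    def has_cognates(self) -> bool:
        first = next(iter(self.entries.values()))
        return first[0][1] is not None

    def forms(self, concept: str) -> tuple[str, ...]:
        return tuple(f for f, _ in self.entries[concept])

    def cognate_classes(self, concept: str) -> frozenset[str]:
        if not self.has_cognates:
            raise ValidationError(
                f"variety {self.variety_id!r} carries no cognate coding"
            )
        return frozenset(c for _, c in self.entries[concept] if c is not None)

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Wordlist):
            return NotImplemented
        return self.variety_id == other.variety_id and self.entries == other.entries

    def __hash__(self) -> int:
        return hash((self.variety_id, tuple(sorted(self.entries.items()))))

    def __repr__(self) -> str:
        return f"Wordlist({self.variety_id!r}, {len(self.entries)} concepts)"


REQUIRED_COLUMNS = ("variety", "concept", "form")


def read_wordlists(path: str | Path, format: str = "long_tsv") -> list[Wordlist]:
    """Read a long/tidy TSV wordlist file into one Wordlist per variety.

    The file must have a header naming columns ``variety``, ``concept`` and
    ``form``; a ``cognate`` column is optional.  Duplicate
    (variety, concept) rows are kept as synonyms.  The returned list is
    sorted by variety id, and forms within a concept are sorted, so the
    result is invariant to input row order.
    """
    if format != "long_tsv":
        raise FormatError(f"unknown wordlist format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_cog_col = "cognate" in df.columns
    per_variety: dict[str, dict[str, list[tuple[str, str | None]]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        variety = getattr(row, "variety")
        concept = getattr(row, "concept")
        form = getattr(row, "form")
        if not form:
            raise ValidationError(f"{path}: empty form at row {i}")
        if not variety or not concept:
            raise ValidationError(f"{path}: empty variety/concept at row {i}")
        cog = getattr(row, "cognate") if has_cog_col else ""
        per_variety.setdefault(variety, {}).setdefault(concept, []).append(
            (form, cog if cog else None)
        )
    return [Wordlist(v, per_variety[v]) for v in sorted(per_variety)]


def write_wordlists(wordlists: Iterable[Wordlist], path: str | Path) -> None:
    """Write wordlists back to the long TSV layout read_wordlists accepts."""
    wordlists = list(wordlists)
    with_cog = any(w.has_cognates for w in wordlists)
    rows = []
    for w in wordlists:
        for concept in sorted(w.entries):
            for form, cog in w.entries[concept]:
                row = {"variety": w.variety_id, "concept": concept, "form": form}
                if with_cog:
                    row["cognate"] = "" if cog is None else cog
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Group maps and trait tables
# ---------------------------------------------------------------------------

def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column variety -> group table (TSV or CSV).

    A header line ``variety<sep>group`` is skipped if present.
    """
    mapping: GroupMap = {}
    for i, (fields, line) in enumerate(_two_column_rows(path), start=1):
        if i == 1 and [f.lower() for f in fields] == ["variety", "group"]:
            continue
        variety, group = fields
        if variety in mapping:
            raise ValidationError(f"{path}: duplicate variety {variety!r} (line {i})")
        mapping[variety] = group
    if not mapping:
        raise FormatError(f"{path}: empty group map")
    return mapping


class TraitTable(dict):
    """group id -> trait value in [0, 1] (e.g. proportion of rice paddies)."""

    def __init__(self, values: Mapping[str, float]):
        checked = {}
        for group, value in values.items():
            value = float(value)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"trait value {value} for group {group!r} outside [0, 1]"
                )
            checked[group] = value
        if not checked:
            raise ValidationError("trait table is empty")
        super().__init__(checked)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a two-column group,value table (CSV or TSV, header optional)."""
    values: dict[str, float] = {}
    for i, (fields, line) in enumerate(_two_column_rows(path), start=1):
        group, raw = fields
        try:
            value = float(raw)
        except ValueError:
            if i == 1:  # header line
                continue
            raise FormatError(f"{path}: non-numeric value {raw!r} at line {i}")
        if group in values:
            raise ValidationError(f"{path}: duplicate group {group!r} (line {i})")
        if not (0.0 <= value <= 1.0):
            raise ValidationError(
                f"{path}: trait value {value} for {group!r} outside [0, 1] (line {i})"
            )
        values[group] = value
    if not values:
        raise FormatError(f"{path}: no trait rows")
    return TraitTable(values)


def write_trait_table(table: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group,value\n")
        for group in table:
            fh.write(f"{group},{table[group]!r}\n")


def _two_column_rows(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            fields = line.split(sep)
            if len(fields) != 2:
                raise FormatError(f"{path}: expected 2 columns, got {len(fields)}")
            yield fields, line


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def write_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Write a labeled distance matrix as square TSV (header + label column).

    Values are written with Python float repr, so read(write(m)) == m
    bit-for-bit (well beyond the 12 significant digits required).
    """
    df = pd.DataFrame(np.asarray(m.data), index=list(m.ids), columns=list(m.ids))
    df.to_csv(path, sep="\t", index_label="")


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labeled TSV distance matrix.

    Symmetry is enforced to within ``ASYMMETRY_TOL``; passing matrices are
    exactly symmetrized. The diagonal must be zero to the same tolerance;
    entries must be non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is not square {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row labels differ from column labels")
    data = df.to_numpy(dtype=float)
    if not np.isfinite(data).all():
        raise FormatError(f"{path}: non-finite entries")
    if np.abs(data - data.T).max() > ASYMMETRY_TOL:
        raise FormatError(
            f"{path}: matrix asymmetric beyond tolerance {ASYMMETRY_TOL}"
        )
    if np.abs(np.diag(data)).max() > ASYMMETRY_TOL:
        raise FormatError(f"{path}: nonzero diagonal")
    if data.min() < -ASYMMETRY_TOL:
        raise FormatError(f"{path}: negative distances")
    data = np.clip((data + data.T) / 2.0, 0.0, None)
    np.fill_diagonal(data, 0.0)
    try:
        return DistanceMatrix(data, [str(i) for i in df.index])
    except DistanceMatrixError as exc:  # pragma: no cover - guarded above
        raise FormatError(f"{path}: {exc}") from exc
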