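"""Taxon abundance tables, normalization, diversity and Bray–Curtis similarity.

The analysis consumes a taxon-by-sample abundance matrix (shotgun profiles
collapsed to species level), converts it to pairwise Bray–Curtis
dissimilarity, and works throughout with *microbiome similarity* defined as
1 − Bray–Curtis. Simpson diversity (1 − Σp²) summarizes single samples.

Two normalizations are provided: ``relative`` (columns to proportions,
the default) and ``median_of_ratios`` (the classic RNA-seq size-factor
formula), the latter as a documented stand-in for a variance-stabilizing
transform whose dispersion fit is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dyad import SimilarityMatrix

__all__ = [
    "AbundanceTable",
    "SampleRecord",
    "AmbiguousSampleError",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "normalize",
    "bray_curtis_similarity",
    "simpson_diversity",
    "bat_similarity_matrix",
    "select_gut",
    "select_latest_faecal",
]

log = logging.getLogger(__name__)

SAMPLE_TYPES = ("faecal", "gut")
PHASES = ("pre_merge", "post_merge")
NORMALIZATION_TAGS = ("raw", "relative", "median_of_ratios")


class AmbiguousSampleError(ValueError):
    """A sample selector matched more than one sample for a bat."""


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one microbiome sample.

    ``day`` is an integer day index since study start; ``phase`` flags
    whether the sample predates the colony merge.
    """

    sample_id: str
    bat_id: str
    colony: str
    day: int
    sample_type: str
    phase: str

    def __post_init__(self):
        if self.day < 0:
            raise ValueError(f"sample {self.sample_id!r}: day must be >= 0")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: sample_type must be one of "
                f"{SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.phase not in PHASES:
            raise ValueError(
                f"sample {self.sample_id!r}: phase must be one of {PHASES}, "
                f"got {self.phase!r}"
            )


class AbundanceTable:
    """Non-negative taxon-by-sample abundance matrix with labels.

    Invariants: all values finite and >= 0; taxon and sample ids unique;
    every sample column has positive sum (all-zero samples are rejected at
    construction rather than silently dropped).
    """

    def __init__(self, taxon_ids, sample_ids, values, normalization_tag="raw"):
        self.taxon_ids = [str(t) for t in taxon_ids]
        self.sample_ids = [str(s) for s in sample_ids]
        self.values = np.array(values, dtype=float)
        if normalization_tag not in NORMALIZATION_TAGS:
            raise ValueError(f"unknown normalization tag {normalization_tag!r}")
        self.normalization_tag = normalization_tag
        self._validate()
        self._col = {s: j for j, s in enumerate(self.sample_ids)}

    def _validate(self):
        t, s = len(self.taxon_ids), len(self.sample_ids)
        if t == 0 or s == 0:
            raise ValueError("empty abundance table")
        if self.values.shape != (t, s):
            raise ValueError(
                f"values shape {self.values.shape} != ({t} taxa, {s} samples)"
            )
        for name, labels in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(labels)) != len(labels):
                dup = sorted({x for x in labels if labels.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dup}")
        bad = ~np.isfinite(self.values) | (self.values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid value {self.values[i, j]} at taxon "
                f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        zero = self.values.sum(axis=0) <= 0
        if zero.any():
            j = int(np.argmax(zero))
            raise ValueError(
                f"sample column {self.sample_ids[j]!r} sums to zero"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        try:
            return self.values[:, self._col[str(sample_id)]]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        cols = [self._col[str(s)] for s in sample_ids]
        return AbundanceTable(
            self.taxon_ids, list(sample_ids), self.values[:, cols],
            self.normalization_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.taxon_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_SPECIES_PREFIX = "s__"
_STRAIN_PREFIX = "t__"


def read_abundance_table(path, dialect: str = "plain_tsv") -> AbundanceTable:
    """Read a taxon-by-sample TSV.

    ``plain_tsv``: first column ``taxon_id``, one column per sample,
    ``#``-prefixed comment lines skipped.

    ``metaphlan_merged``: merged-profile dialect where the first column is a
    full lineage string (``k__...|g__...|s__...``); only rows whose deepest
    rank is species are kept, the lineage prefix is stripped to the species
    name, and values are treated as already-normalized relative abundances.
    An ``NCBI_tax_id``-style second column, if present, is ignored.
    """
    if dialect not in ("plain_tsv", "metaphlan_merged"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty or single-column abundance table")
    df = df.set_index(df.columns[0])
    tag = "raw"
    if dialect == "metaphlan_merged":
        drop = [c for c in df.columns if c.lower() in ("ncbi_tax_id", "clade_taxid")]
        df = df.drop(columns=drop)
        keep = []
        for lineage in df.index:
            last = str(lineage).split("|")[-1]
            keep.append(last.startswith(_SPECIES_PREFIX))
        df = df.loc[keep]
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no species-level rows in metaphlan table")
        df.index = [
            str(l).split("|")[-1][len(_SPECIES_PREFIX):] for l in df.index
        ]
        tag = "relative"
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    return AbundanceTable(list(df.index), list(df.columns), values, tag)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id",
                            float_format="%.17g")


_META_COLS = ["sample_id", "bat_id", "colony", "day", "sample_type", "phase"]


def read_sample_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    records = [
        SampleRecord(
            sample_id=row.sample_id, bat_id=row.bat_id, colony=row.colony,
            day=int(row.day), sample_type=row.sample_type, phase=row.phase,
        )
        for row in df.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample_id {dup}")
    return records


def write_sample_metadata(samples: Iterable[SampleRecord], path) -> None:
    pd.DataFrame([s.__dict__ for s in samples])[_META_COLS].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(table: AbundanceTable, method: str) -> AbundanceTable:
    """Return a column-normalized copy of *table*.

    ``relative``
        Each sample column is divided by its sum (proportions; idempotent).
    ``median_of_ratios``
        Each column is divided by its size factor: the median, over taxa with
        a nonzero geometric mean across samples, of count / geometric mean.
        Requires at least one taxon nonzero in every sample.
    """
    if method == "relative":
        values = table.values / table.values.sum(axis=0, keepdims=True)
        return AbundanceTable(table.taxon_ids, table.sample_ids, values,
                              "relative")
    if method == "median_of_ratios":
        v = table.values
        allpos = (v > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "median_of_ratios: no taxon is nonzero in all samples; "
                "add a pseudo-count or use the 'relative' method"
            )
        ref = v[allpos]
        geomean = np.exp(np.log(ref).mean(axis=1))
        size_factors = np.median(ref / geomean[:, None], axis=0)
        values = v / size_factors
        return AbundanceTable(table.taxon_ids, table.sample_ids, values,
                              "median_of_ratios")
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# Diversity and similarity
# ---------------------------------------------------------------------------

def simpson_diversity(table: AbundanceTable, sample_id: str) -> float:
    """Simpson diversity 1 − Σp² of one sample (probability two random
    reads come from different taxa); in [0, 1)."""
    col = table.column(sample_id)
    p = col / col.sum()
    return float(1.0 - np.sum(p * p))


def bray_curtis_similarity(
    table: AbundanceTable, sample_subset: Optional[Sequence[str]] = None
) -> SimilarityMatrix:
    """Pairwise microbiome similarity S = 1 − Bray–Curtis dissimilarity.

    BC(u, v) = Σ|u−v| / Σ(u+v) over taxa; S is symmetric with unit diagonal.
    """
    sub = table if sample_subset is None else table.subset_samples(sample_subset)
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples for a similarity matrix")
    # all-zero columns already rejected by AbundanceTable
    dist = squareform(pdist(sub.values.T, metric="braycurtis"))
    return SimilarityMatrix(sub.sample_ids, 1.0 - dist)


# ---------------------------------------------------------------------------
# Sample-to-bat mapping
# ---------------------------------------------------------------------------

def select_gut(records: Sequence[SampleRecord]) -> Optional[SampleRecord]:
    """Selector: the bat's single final gut sample (error if several)."""
    guts = [r for r in records if r.sample_type == "gut"]
    if len(guts) > 1:
        raise AmbiguousSampleError(
            f"bat {guts[0].bat_id!r} has {len(guts)} gut samples: "
            f"{[g.sample_id for g in guts]}"
        )
    return guts[0] if guts else None


def select_latest_faecal(cutoff_day: Optional[int] = None) -> Callable:
    """Selector factory: the bat's latest faecal sample at or before
    *cutoff_day* (no cutoff if None). Two samples on the tie day is an error."""

    def _select(records: Sequence[SampleRecord]) -> Optional[SampleRecord]:
        cands = [
            r for r in records
            if r.sample_type == "faecal"
            and (cutoff_day is None or r.day <= cutoff_day)
        ]
        if not cands:
            return None
        best_day = max(r.day for r in cands)
        best = [r for r in cands if r.day == best_day]
        if len(best) > 1:
            raise AmbiguousSampleError(
                f"bat {best[0].bat_id!r} has {len(best)} faecal samples on "
                f"day {best_day}: {[b.sample_id for b in best]}"
            )
        return best[0]

    return _select


def bat_similarity_matrix(
    sim: SimilarityMatrix,
    samples: Sequence[SampleRecord],
    selector: Callable[[Sequence[SampleRecord]], Optional[SampleRecord]],
) -> tuple[SimilarityMatrix, dict]:
    """Collapse a sample-level similarity matrix to one row/column per bat.

    *selector* maps a bat's sample records to at most one chosen sample (or
    raises :class:`AmbiguousSampleError`). Bats without a selected sample are
    dropped and listed in the returned provenance dict under ``"dropped"``;
    chosen sample ids are recorded under ``"selected"``.
    """
    known = set(sim.ids)
    by_bat: dict[str, list[SampleRecord]] = {}
    for rec in samples:
        if rec.sample_id in known:
            by_bat.setdefault(rec.bat_id, []).append(rec)
    selected: dict[str, str] = {}
    dropped: list[str] = []
    for bat in sorted(by_bat):
        pick = selector(by_bat[bat])
        if pick is None:
            dropped.append(bat)
        else:
            selected[bat] = pick.sample_id
    if len(selected) < 2:
        raise ValueError(
            f"selector retained {len(selected)} bats; need at least 2"
        )
    if dropped:
        log.info("bat_similarity_matrix: dropped bats with no selected "
                 "sample: %s", dropped)
    bats = sorted(selected)
    idx = [sim.index_of(selected[b]) for b in bats]
    values = sim.values[np.ix_(idx, idx)]
    provenance = {"selected": selected, "dropped": dropped}
    return SimilarityMatrix(bats, values), provenance
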