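"""Polygenic risk score construction.

Builds the 313-variant breast-cancer PRS as a weighted sum of risk-allele
dosages, for the overall score and the two estrogen-receptor-specific
(ER-positive / ER-negative) scores, then standardizes each score to
standard-deviation units and assigns population quartiles.

Weights files are tab-separated with header columns
``id, chr, pos, effect_allele, other_allele`` plus one column per score
(``weight_overall, weight_er_pos, weight_er_neg``) holding per-effect-allele
log odds ratios — a documented superset of the PGS Catalog scoring-file
layout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tdluprs.prs")

SCORE_LABELS = ("overall", "ER_positive", "ER_negative")

#: weight-file column backing each score label
WEIGHT_COLUMNS = {
    "overall": "weight_overall",
    "ER_positive": "weight_er_pos",
    "ER_negative": "weight_er_neg",
}

_MANDATORY_COLUMNS = ("id", "effect_allele", "other_allele")

#: strand-ambiguous allele pairs (indistinguishable under strand flip)
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class VariantWeight:
    """One variant's contribution to a score: per-effect-allele log OR."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: weight {self.weight!r} not finite")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _AMBIGUOUS_PAIRS


@dataclass
class WeightSet:
    """An ordered collection of variant weights for one score label."""

    score_label: str
    weights: list[VariantWeight]

    def __post_init__(self) -> None:
        ids = [w.variant_id for w in self.weights]
        if len(set(ids)) != len(ids):
            dup = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant ids in weight set: {dup}")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def variant_ids(self) -> list[str]:
        return [w.variant_id for w in self.weights]

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([w.weight for w in self.weights], dtype=float)


def load_weight_file(path) -> dict[str, WeightSet]:
    """Parse a tab-separated weights file into one WeightSet per score column.

    Rows whose weight cell is missing/unparseable are dropped from that score
    only, with a logged count. Duplicate variant ids are a hard error.
    """
    table = pd.read_csv(path, sep="\t", dtype={"id": str, "chr": str})
    for col in _MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"weights file {path} is missing mandatory column {col!r}")
    weight_cols = [c for c in table.columns if c.startswith("weight")]
    if not weight_cols:
        raise ValueError(f"weights file {path} has no weight column")
    dups = table["id"][table["id"].duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate variant id(s) in {path}: {sorted(dups)}")

    label_for = {v: k for k, v in WEIGHT_COLUMNS.items()}
    sets: dict[str, WeightSet] = {}
    for col in weight_cols:
        label = label_for.get(col, col)
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            logger.warning(
                "%s: dropped %d row(s) with unparseable %s", path, int(bad.sum()), col
            )
        kept = table.loc[~bad]
        sets[label] = WeightSet(
            score_label=label,
            weights=[
                VariantWeight(
                    variant_id=row["id"],
                    chrom=str(row.get("chr", "")),
                    pos=int(row.get("pos", 0) or 0),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    weight=float(values.loc[idx]),
                )
                for idx, row in kept.iterrows()
            ],
        )
    return sets


def write_weight_file(path, table: pd.DataFrame) -> None:
    """Write a weights table (columns per the documented layout) as TSV."""
    table.to_csv(path, sep="\t", index=False)


def harmonize_dosages(
    dosages: pd.DataFrame, counted_alleles: dict[str, str], weights: WeightSet
) -> pd.DataFrame:
    """Flip dosages to count the weight file's effect allele.

    ``counted_alleles`` maps variant id to the allele the dosage column
    counts. Where that is the weight's other_allele the dosage becomes
    ``2 - d``. Strand-ambiguous variants (A/T, C/G) cannot be checked by
    allele match and are resolved by id only, with a logged warning.
    """
    out = dosages.copy()
    flipped, ambiguous = [], []
    for w in weights.weights:
        if w.variant_id not in out.columns:
            continue
        counted = counted_alleles.get(w.variant_id)
        if counted is None:
            continue
        if w.is_strand_ambiguous:
            ambiguous.append(w.variant_id)
            continue
        if counted == w.other_allele:
            out[w.variant_id] = 2.0 - out[w.variant_id]
            flipped.append(w.variant_id)
        elif counted != w.effect_allele:
            raise ValueError(
                f"{w.variant_id}: counted allele {counted!r} matches neither "
                f"effect ({w.effect_allele!r}) nor other ({w.other_allele!r}) allele"
            )
    if flipped:
        logger.info("flipped dosage orientation for %d variant(s)", len(flipped))
    if ambiguous:
        logger.warning(
            "%d strand-ambiguous variant(s) matched by id only: %s%s",
            len(ambiguous),
            ", ".join(ambiguous[:5]),
            "..." if len(ambiguous) > 5 else "",
        )
    return out


def compute_raw_prs(dosages: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Weighted dosage sum per sample: score_i = sum_j w_j * d_ij.

    ``dosages`` has one column per variant id (values in [0, 2] or NaN).
    Missing dosages are mean-imputed per variant before summation.
    """
    missing = [v for v in weights.variant_ids if v not in dosages.columns]
    if missing:
        raise KeyError(
            f"{len(missing)} weight variant(s) absent from dosage matrix: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    mat = dosages[weights.variant_ids].to_numpy(dtype=float)
    if np.isnan(mat).any():
        col_means = np.nanmean(mat, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)  # all-missing column
        idx = np.where(np.isnan(mat))
        mat[idx] = col_means[idx[1]]
    finite = mat[np.isfinite(mat)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return pd.Series(mat @ weights.weight_vector, index=dosages.index, name="prs_raw")


def standardize_scores(raw) -> np.ndarray:
    """Affine-transform scores to sample mean 0, sample SD 1 (denominator n-1)."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("scores are constant; cannot standardize (zero variance)")
    return (x - x.mean()) / sd


def assign_quartiles(standardized) -> np.ndarray:
    """Assign Q1..Q4 by the pooled 25/50/75th percentiles (linear interpolation).

    Intervals are left-open right-closed except the first; a value equal to a
    cut point goes to the lower category.
    """
    x = np.asarray(standardized, dtype=float)
    if x.size == 0:
        raise ValueError("no scores to categorize")
    cuts = np.percentile(x, [25, 50, 75])
    codes = np.searchsorted(cuts, x, side="left")
    if np.all(x == x[0]):
        logger.warning("all scores tied; every sample assigned Q1")
        codes = np.zeros_like(codes)
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    return labels[codes]


def build_score_table(
    dosages: pd.DataFrame,
    weight_sets: dict[str, WeightSet],
    subject_ids=None,
) -> pd.DataFrame:
    """Per-sample score table: raw, standardized, and quartile per score label."""
    out = pd.DataFrame(index=dosages.index)
    out["subject_id"] = (
        list(subject_ids) if subject_ids is not None else dosages.index.astype(str)
    )
    for label, ws in weight_sets.items():
        raw = compute_raw_prs(dosages, ws)
        std = standardize_scores(raw)
        out[f"prs_raw_{label}"] = raw.to_numpy()
        out[f"prs_std_{label}"] = std
        out[f"prs_quartile_{label}"] = assign_quartiles(std)
    return out.reset_index(drop=True)
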