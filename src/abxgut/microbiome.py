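"""Microbiome count-table preparation: rarefaction, alpha diversity, CLR.

Diversity metrics (Shannon index in nats, species richness, inverse Simpson)
are computed on rarefied counts; species-level models consume centered
log-ratio (CLR) transformed relative abundances from the unrarefied table.
Zero handling in the CLR follows a two-step convention: a single global
pseudo-value (the smallest strictly positive entry of the matrix) is added
before the log transform, and entries that were zero before transformation
are then overwritten with the per-species minimum CLR value among originally
non-zero entries, so that all initial zeros of one species share one
transformed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("abxgut")


def rarefy(counts_row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one count vector without replacement to a fixed depth.

    Multivariate-hypergeometric draw: the output sums to ``depth`` and no
    entry exceeds its input. ``depth`` greater than the row total is an
    error.
    """
    row = np.asarray(counts_row)
    total = int(row.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    return rng.multivariate_hypergeometric(row.astype(np.int64), depth)


def rarefy_table(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Rarefy every row of a participants x species count table."""
    rng = np.random.default_rng(seed)
    out = np.empty(counts.shape, dtype=np.int64)
    values = counts.to_numpy()
    for i in range(len(counts)):
        total = int(values[i].sum())
        if depth > total:
            raise ValueError(
                f"rarefaction depth {depth} exceeds total {total} for sample "
                f"{counts.index[i]!r}"
            )
        out[i] = rng.multivariate_hypergeometric(values[i].astype(np.int64), depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def alpha_diversity(row: np.ndarray) -> tuple[float, int, float]:
    """(Shannon in nats, richness, inverse Simpson) for one count/abundance row.

    With p_i = n_i / N over the strictly positive entries:
    Shannon = -sum p_i ln p_i; richness = #{i : n_i > 0};
    inverse Simpson = 1 / sum p_i^2. An all-zero row is an error.
    """
    row = np.asarray(row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("alpha_diversity: all-zero row")
    pos = row[row > 0]
    p = pos / total
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p**2).sum())
    return shannon, int(pos.size), inv_simpson


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-participant diversity metrics from a count/abundance table."""
    vals = counts.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0][0]
        raise ValueError(f"diversity_table: all-zero row for sample {bad!r}")
    p = vals / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return pd.DataFrame(
        {
            "shannon": -plogp.sum(axis=1),
            "richness": (vals > 0).sum(axis=1),
            "inv_simpson": 1.0 / (p**2).sum(axis=1),
        },
        index=counts.index,
    )


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize rows so each sums to 100 (percent relative abundance)."""
    vals = counts.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0][0]
        raise ValueError(f"relative_abundance: all-zero row for sample {bad!r}")
    return pd.DataFrame(
        100.0 * vals / totals[:, None], index=counts.index, columns=counts.columns
    )


def clr_transform(relabund: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform with shared-zero replacement.

    Steps: (1) delta = smallest strictly positive entry of the whole matrix;
    (2) add delta everywhere; (3) per row, subtract the mean log (the log of
    the geometric mean); (4) per species column, overwrite every entry that
    was zero before the transform with the minimum CLR value among that
    column's originally non-zero entries — all initial zeros of a species
    share one value. A species column with no non-zero entry is an error
    (prevalence-filter first).
    """
    X = relabund.to_numpy(dtype=float)
    zero_mask = X == 0
    all_zero_cols = zero_mask.all(axis=0)
    if all_zero_cols.any():
        bad = list(relabund.columns[all_zero_cols][:5])
        raise ValueError(
            f"clr_transform: species with no non-zero entries (e.g. {bad}); "
            "apply a prevalence filter first"
        )
    positive = X[X > 0]
    if positive.size == 0:
        raise ValueError("clr_transform: empty or all-zero matrix")
    delta = positive.min()
    L = np.log(X + delta)
    clr = L - L.mean(axis=1, keepdims=True)
    masked = np.where(zero_mask, np.inf, clr)
    col_min_nonzero = masked.min(axis=0)
    clr = np.where(zero_mask, col_min_nonzero[None, :], clr)
    return pd.DataFrame(clr, index=relabund.index, columns=relabund.columns)


def prevalence_filter(
    relabund_tables: Sequence[pd.DataFrame],
    threshold: float = 0.02,
    mode: str = "pooled",
) -> list[str]:
    """Species to retain by prevalence across cohort tables.

    ``mode="pooled"`` (default): retain species whose fraction of all
    participants (cohorts concatenated) with a positive entry is strictly
    greater than ``threshold``. ``mode="per_cohort"``: the species must
    exceed the threshold in every cohort table.
    """
    if not relabund_tables or any(len(t) == 0 for t in relabund_tables):
        raise ValueError("prevalence_filter: empty table(s)")
    species = relabund_tables[0].columns
    for t in relabund_tables[1:]:
        if not t.columns.equals(species):
            raise ValueError("prevalence_filter: tables share no common species namespace")
    if mode == "pooled":
        pooled = pd.concat(relabund_tables, axis=0)
        prev = (pooled > 0).mean(axis=0)
        keep = prev > threshold
    elif mode == "per_cohort":
        keep = pd.Series(True, index=species)
        for t in relabund_tables:
            keep &= (t > 0).mean(axis=0) > threshold
    else:
        raise ValueError(f"prevalence_filter: unknown mode {mode!r}")
    retained = list(species[keep])
    logger.info(
        "prevalence_filter: retained %d of %d species (threshold=%g, mode=%s)",
        len(retained), len(species), threshold, mode,
    )
    return retained


@dataclass
class AbundanceBundle:
    """Prepared microbiome data for one cohort.

    counts: raw counts; rarefied: counts subsampled to a common depth;
    relabund: rows summing to 100; clr: CLR-transformed relative abundances
    of retained species; diversity: per-participant shannon/richness/
    inv_simpson (computed on the rarefied table).
    """

    counts: pd.DataFrame
    rarefied: pd.DataFrame
    relabund: pd.DataFrame
    clr: pd.DataFrame
    diversity: pd.DataFrame


def prepare_cohort(
    counts: pd.DataFrame,
    retained_species: Sequence[str],
    depth: int,
    seed: int,
) -> AbundanceBundle:
    """Full preparation for one cohort count table."""
    rarefied = rarefy_table(counts, depth=depth, seed=seed)
    relabund = relative_abundance(counts)
    clr = clr_transform(relabund[list(retained_species)])
    diversity = diversity_table(rarefied)
    return AbundanceBundle(
        counts=counts, rarefied=rarefied, relabund=relabund, clr=clr, diversity=diversity
    )
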