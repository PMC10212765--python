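"""Paired cohort analytics over matched primary/recurrent samples.

Three descriptive summaries per cohort: the paired difference in lineage
abundance (mean over pairs of recurrent minus primary fraction), the
per-(lineage, marker) log2 fold change of mean signal intensity
(recurrent over primary, averaged across pairs), and the Spearman
co-infiltration correlation matrix over lineage abundances within each
condition.  With a handful of pairs these are descriptive statistics —
an optional Wilcoxon signed-rank flag refuses cohorts smaller than six
pairs rather than report meaningless p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import intensity_col

logger = logging.getLogger(__name__)

MIN_WILCOXON_PAIRS = 6


def _check_pairs(abundances: pd.DataFrame, pairs: dict[str, tuple[str, str]]):
    samples = set(abundances["sample_id"].unique())
    for pid, (prim, rec) in pairs.items():
        missing = {prim, rec} - samples
        if missing:
            raise ValidationError(
                f"pair {pid!r}: sample(s) {sorted(missing)} absent from table")


def paired_abundance_diff(
    abundances: pd.DataFrame,
    pairs: dict[str, tuple[str, str]],
    wilcoxon: bool = False,
) -> pd.DataFrame:
    """Mean over pairs of (recurrent - primary) lineage fraction.

    ``abundances`` is the long-format output of
    :func:`imcspatial.phenotype.abundance_table`; ``pairs`` maps pair id
    to (primary sample, recurrent sample).  Lineages absent from a sample
    contribute fraction 0.
    """
    _check_pairs(abundances, pairs)
    wide = abundances.pivot_table(
        index="sample_id", columns="lineage", values="fraction", fill_value=0.0)
    lineages = list(wide.columns)
    rows = []
    for lin in lineages:
        diffs = [
            wide.at[rec, lin] - wide.at[prim, lin]
            for prim, rec in pairs.values()
        ]
        row = {
            "lineage": lin,
            "abundance_diff": float(np.mean(diffs)),
            "n_pairs": len(diffs),
        }
        if wilcoxon:
            if len(diffs) < MIN_WILCOXON_PAIRS:
                raise ValidationError(
                    f"Wilcoxon signed-rank needs >= {MIN_WILCOXON_PAIRS} pairs, "
                    f"got {len(diffs)}")
            row["wilcoxon_p"] = float(stats.wilcoxon(diffs).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def marker_log2fc(
    cells_by_sample: dict[str, pd.DataFrame],
    pairs: dict[str, tuple[str, str]],
    lineage: str,
    marker: str,
    min_cells: int = 10,
) -> dict:
    """log2 fold change of mean marker intensity in one lineage.

    Per pair: log2(mean raw intensity over the lineage's cells in the
    recurrent sample / same in the primary).  Pairs in which the lineage
    has fewer than ``min_cells`` cells on either side, or a zero primary
    mean, are dropped with a logged note.  Returns a dict with the mean
    over surviving pairs (``log2fc``), per-pair values, and
    ``defined=False`` when no pair survives.
    """
    col = intensity_col(marker)
    per_pair: dict[str, float] = {}
    for pid, (prim, rec) in pairs.items():
        for sid in (prim, rec):
            if sid not in cells_by_sample:
                raise ValidationError(f"pair {pid!r}: sample {sid!r} missing")
        sub_p = cells_by_sample[prim].query("lineage == @lineage")
        sub_r = cells_by_sample[rec].query("lineage == @lineage")
        if len(sub_p) < min_cells or len(sub_r) < min_cells:
            logger.info(
                "pair %s dropped for (%s, %s): %d/%d cells < min_cells=%d",
                pid, lineage, marker, len(sub_p), len(sub_r), min_cells)
            continue
        mean_p = float(sub_p[col].mean())
        mean_r = float(sub_r[col].mean())
        if mean_p <= 0:
            logger.info("pair %s dropped for (%s, %s): zero primary mean",
                        pid, lineage, marker)
            continue
        per_pair[pid] = float(np.log2(mean_r / mean_p))
    defined = len(per_pair) > 0
    return {
        "lineage": lineage,
        "marker": marker,
        "log2fc": float(np.mean(list(per_pair.values()))) if defined else np.nan,
        "per_pair": per_pair,
        "n_pairs_used": len(per_pair),
        "defined": defined,
    }


def marker_log2fc_table(
    cells_by_sample, pairs, lineage_markers: list[tuple[str, str]],
    min_cells: int = 10,
) -> pd.DataFrame:
    rows = []
    for lineage, marker in lineage_markers:
        res = marker_log2fc(cells_by_sample, pairs, lineage, marker, min_cells)
        res.pop("per_pair")
        rows.append(res)
    return pd.DataFrame(rows)


def abundance_spearman(
    abundances: pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Spearman co-infiltration matrix over lineage abundances.

    Tie-averaged rank correlation between every lineage pair across the
    given samples (a condition group).  Requires >= 3 samples; the
    diagonal is 1 and pairs where either lineage has zero variance get
    NaN (undefined, flagged by absence of a finite value).
    """
    wide = abundances.pivot_table(
        index="sample_id", columns="lineage", values="fraction", fill_value=0.0)
    if samples is not None:
        missing = set(samples) - set(wide.index)
        if missing:
            raise ValidationError(f"samples absent from table: {sorted(missing)}")
        wide = wide.loc[samples]
    if len(wide) < 3:
        raise ValidationError(
            f"Spearman correlation needs >= 3 samples, got {len(wide)}")
    lineages = list(wide.columns)
    k = len(lineages)
    mat = np.eye(k)
    values = wide.to_numpy()
    sds = values.std(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            if sds[i] == 0 or sds[j] == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(values[:, i], values[:, j]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=lineages, columns=lineages)
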