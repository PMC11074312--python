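"""qPCR normalisation and randomized-block ANOVA with Tukey contrasts.

Input is a long table of N0 starting quantities (one row per gene x
condition x biological replicate; N0 comes from amplification-curve software
and is taken as given).  Normalisation divides each target gene's N0 by the
geometric mean of the housekeeping genes measured in the same sample,
log2-transforms, and relativises to the mean of the control condition's
replicates, so the control averages exactly zero per gene.

Condition effects are tested by randomized-block-design (RBD) ANOVA — a
two-way additive model, condition + replicate block, no interaction — with
Tukey's HSD for pairwise contrasts and a compact letter display (conditions
sharing a letter are not significantly different at the chosen alpha).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_expression", "rbd_anova_tukey", "compact_letter_display"]


def normalize_expression(
    table: pd.DataFrame,
    housekeeping: tuple[str, ...] = ("GAPDH", "PGK1"),
    control_condition: str = "2i+LIF",
    *,
    gene_col: str = "gene",
    condition_col: str = "condition",
    block_col: str = "replicate",
    value_col: str = "N0",
) -> pd.DataFrame:
    """Housekeeping-normalised, log2, control-relative expression per sample.

    Returns one row per target gene x sample with ``rel_log2_expr``.  The
    normalisation is invariant to any common factor multiplying all N0 values
    of a sample (it cancels in the ratio).  Zero or negative N0 values and
    samples missing a housekeeping gene are errors.
    """
    for col in (gene_col, condition_col, block_col, value_col):
        if col not in table.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    if (table[value_col] <= 0).any():
        bad = table.loc[table[value_col] <= 0]
        raise ValueError(f"N0 must be positive; offending rows: {bad.index.tolist()}")
    if control_condition not in set(table[condition_col]):
        raise ValueError(f"control condition {control_condition!r} not in table")

    hk = table[table[gene_col].isin(housekeeping)]
    geo = {}
    for (cond, block), sub in hk.groupby([condition_col, block_col]):
        present = set(sub[gene_col])
        missing = set(housekeeping) - present
        if missing:
            raise ValueError(
                f"sample ({cond}, replicate {block}) missing housekeeping genes "
                f"{sorted(missing)}"
            )
        geo[(cond, block)] = float(stats.gmean(sub[value_col]))

    targets = table[~table[gene_col].isin(housekeeping)].copy()
    keys = list(zip(targets[condition_col], targets[block_col]))
    missing_samples = sorted({k for k in keys if k not in geo})
    if missing_samples:
        raise ValueError(f"samples without housekeeping measurements: {missing_samples}")
    targets["log2_ratio"] = np.log2(
        targets[value_col].to_numpy() / np.array([geo[k] for k in keys])
    )
    out = []
    for gene, sub in targets.groupby(gene_col):
        ctrl = sub.loc[sub[condition_col] == control_condition, "log2_ratio"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no {control_condition!r} control samples")
        rel = sub.copy()
        rel["rel_log2_expr"] = sub["log2_ratio"] - ctrl.mean()
        out.append(rel)
    return (
        pd.concat(out)[[gene_col, condition_col, block_col, "rel_log2_expr"]]
        .reset_index(drop=True)
    )


def _anova_rbd(values: np.ndarray, cond_idx: np.ndarray, block_idx: np.ndarray):
    """Closed-form balanced two-way additive ANOVA (one observation per cell)."""
    k = cond_idx.max() + 1
    b = block_idx.max() + 1
    grand = values.mean()
    cond_means = np.array([values[cond_idx == c].mean() for c in range(k)])
    block_means = np.array([values[block_idx == j].mean() for j in range(b)])
    ss_cond = b * np.sum((cond_means - grand) ** 2)
    ss_block = k * np.sum((block_means - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_block, 0.0)
    df_cond, df_err = k - 1, (k - 1) * (b - 1)
    mse = ss_err / df_err
    return cond_means, ss_cond, df_cond, mse, df_err


def rbd_anova_tukey(
    data: pd.DataFrame,
    *,
    value_col: str = "rel_log2_expr",
    condition_col: str = "condition",
    block_col: str = "replicate",
    alpha: float = 0.05,
) -> dict:
    """RBD ANOVA (condition + block) with Tukey HSD and letter groups.

    Requires complete blocks: every condition measured once in every block
    (no imputation).  Returns the condition F statistic and p-value, the
    pairwise Tukey table, per-condition means, and the compact letter
    display.  When all condition means coincide exactly, F = 0 and a single
    letter is shared.
    """
    for col in (value_col, condition_col, block_col):
        if col not in data.columns:
            raise ValueError(f"data missing column {col!r}")
    conditions = sorted(data[condition_col].unique())
    blocks = sorted(data[block_col].unique())
    k, b = len(conditions), len(blocks)
    if k < 2 or b < 2:
        raise ValueError("need >= 2 conditions and >= 2 blocks")
    counts = data.groupby([condition_col, block_col]).size()
    expected = {(c, j) for c in conditions for j in blocks}
    if set(counts.index) != expected or (counts != 1).any():
        raise ValueError(
            "incomplete block design: every condition must appear exactly once "
            "in every block"
        )
    ordered = data.sort_values([condition_col, block_col])
    values = ordered[value_col].to_numpy(dtype=float)
    cond_idx = ordered[condition_col].map({c: i for i, c in enumerate(conditions)}).to_numpy()
    block_idx = ordered[block_col].map({j: i for i, j in enumerate(blocks)}).to_numpy()

    cond_means, ss_cond, df_cond, mse, df_err = _anova_rbd(values, cond_idx, block_idx)
    if ss_cond <= 1e-12 * max(1.0, np.abs(values).max() ** 2):
        f_stat, p_value = 0.0, 1.0
    elif mse == 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = (ss_cond / df_cond) / mse
        p_value = float(stats.f.sf(f_stat, df_cond, df_err))

    se = np.sqrt(mse / b)
    pairs = []
    for i, j in combinations(range(k), 2):
        diff = cond_means[i] - cond_means[j]
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_err))
        pairs.append((conditions[i], conditions[j], float(diff), p_adj, p_adj < alpha))
    tukey = pd.DataFrame(
        pairs, columns=["condition_a", "condition_b", "mean_diff", "p_adj", "significant"]
    )
    letters = compact_letter_display(conditions, cond_means, tukey)
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "df": (df_cond, df_err),
        "mse": float(mse),
        "means": dict(zip(conditions, cond_means.astype(float))),
        "tukey": tukey,
        "letters": letters,
    }


def compact_letter_display(
    conditions: list, means: np.ndarray, tukey: pd.DataFrame
) -> dict:
    """Assign letters so conditions sharing one are not significantly different.

    Because Tukey significance depends only on the distance between means,
    the non-significant sets are contiguous runs of the mean-sorted
    conditions; each maximal run gets one letter.
    """
    sig = {
        frozenset((a_, b_)): s
        for a_, b_, s in zip(tukey["condition_a"], tukey["condition_b"], tukey["significant"])
    }
    order = np.argsort(means)[::-1]  # highest mean first, letters from 'a'
    sorted_conds = [conditions[i] for i in order]
    runs = []
    n = len(sorted_conds)
    for i in range(n):
        j = i
        while j + 1 < n and all(
            not sig[frozenset((sorted_conds[x], sorted_conds[j + 1]))]
            for x in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    # drop runs nested in another run
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in runs)
    ]
    letters: dict = {c: "" for c in conditions}
    for letter_idx, (i, j) in enumerate(sorted(set(maximal))):
        letter = chr(ord("a") + letter_idx)
        for c in sorted_conds[i : j + 1]:
            letters[c] += letter
    return letters
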