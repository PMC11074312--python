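"""Peak-to-gene assignment and the bootstrap overlap-enrichment test.

The question: are differentially expressed (DE) genes enriched for ChIP
binding peaks of a transcription factor?  Peaks are assigned to genes by a
basal-plus-extension regulatory-domain rule (each TSS gets a strand-aware
basal domain, 5 kb upstream / 1 kb downstream by default, extended toward the
neighbouring genes' basal domains up to 1 Mb); a gene "has a peak" when any
peak overlaps its domain.  The enrichment null is built by repeatedly drawing
random gene sets of the DE-list size from the universe and counting
peak-bearing genes; the empirical p-value uses the add-one convention so it
can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "regulatory_domains",
    "assign_peaks_to_genes",
    "bootstrap_overlap",
    "screen_persistent_tfs",
]


@dataclass
class EnrichmentConfig:
    """Bootstrap settings: draw size, iterations, sampling mode, seed."""

    n_draw: int = 292
    n_iter: int = 10_000
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self):
        if self.n_draw < 1 or self.n_iter < 1:
            raise ValueError("n_draw and n_iter must be positive")


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    empirical_p: float
    null_counts: np.ndarray

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "empirical_p": self.empirical_p,
        }


def regulatory_domains(
    genes: pd.DataFrame,
    *,
    basal_up_bp: int = 5000,
    basal_down_bp: int = 1000,
    extension_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domain per gene (0-based half-open).

    The basal domain runs ``basal_up_bp`` upstream to ``basal_down_bp``
    downstream of the TSS, respecting strand.  Each domain is then extended
    in both directions up to ``extension_bp`` from the TSS, stopping at the
    neighbouring genes' basal domains (domains never shrink below basal).
    """
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")
    if (genes["tss"] < 0).any():
        raise ValueError("TSS coordinates must be >= 0")
    out = genes.copy()
    plus = out["strand"].to_numpy() == "+"
    tss = out["tss"].to_numpy()
    basal_start = np.where(plus, tss - basal_up_bp, tss - basal_down_bp + 1)
    basal_end = np.where(plus, tss + basal_down_bp, tss + basal_up_bp + 1)
    basal_start = np.clip(basal_start, 0, None)
    out["basal_start"], out["basal_end"] = basal_start, basal_end

    dom_start = np.clip(tss - extension_bp, 0, None)
    dom_end = tss + extension_bp
    for chrom, idx in out.groupby("chrom").groups.items():
        sub = out.loc[idx].sort_values("tss")
        order = sub.index.to_numpy()
        bs = sub["basal_start"].to_numpy()
        be = sub["basal_end"].to_numpy()
        for k, i in enumerate(order):
            lo, hi = dom_start[out.index.get_loc(i)], dom_end[out.index.get_loc(i)]
            if k > 0:
                lo = max(lo, be[k - 1])
            if k < len(order) - 1:
                hi = min(hi, bs[k + 1])
            # extension never cuts into the gene's own basal domain
            dom_start[out.index.get_loc(i)] = min(lo, bs[k])
            dom_end[out.index.get_loc(i)] = max(hi, be[k])
    out["domain_start"], out["domain_end"] = dom_start.astype(int), dom_end.astype(int)
    return out


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    basal_up_bp: int = 5000,
    basal_down_bp: int = 1000,
    extension_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Flag every gene whose regulatory domain overlaps at least one peak.

    ``peaks`` needs (chrom, start, end) in 0-based half-open coordinates;
    overlap is half-open.  Returns the gene table with domain coordinates and
    a boolean ``has_peak`` column.
    """
    for col in ("chrom", "start", "end"):
        if col not in peaks.columns:
            raise ValueError(f"peak table missing column {col!r}")
    domains = regulatory_domains(
        genes,
        basal_up_bp=basal_up_bp,
        basal_down_bp=basal_down_bp,
        extension_bp=extension_bp,
    )
    has_peak = np.zeros(len(domains), dtype=bool)
    for chrom, pk in peaks.groupby("chrom"):
        sel = domains["chrom"] == chrom
        if not sel.any():
            continue
        ds = domains.loc[sel, "domain_start"].to_numpy()
        de = domains.loc[sel, "domain_end"].to_numpy()
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        # half-open overlap: peak.start < domain.end and peak.end > domain.start
        hit = (ps[None, :] < de[:, None]) & (pe[None, :] > ds[:, None])
        has_peak[np.flatnonzero(sel.to_numpy())] |= hit.any(axis=1)
    domains["has_peak"] = has_peak
    return domains


def bootstrap_overlap(
    de_genes: list[str], universe: pd.DataFrame, cfg: EnrichmentConfig | None = None
) -> EnrichmentResult:
    """Bootstrap test of DE-gene / peak overlap against random gene sets.

    ``observed`` counts DE genes flagged ``has_peak`` in the universe.  The
    null draws ``len(de_genes)`` genes from the universe ``n_iter`` times
    (without replacement within a draw by default, i.e. random gene *sets*)
    and counts flagged genes.  Fold = observed / null mean; empirical p =
    (r + 1) / (n_iter + 1) with r the number of null counts >= observed.
    """
    cfg = cfg or EnrichmentConfig()
    if "has_peak" not in universe.columns:
        raise ValueError("universe must carry a has_peak column (run assign_peaks_to_genes)")
    ids = pd.Index(universe["gene_id"])
    missing = sorted(set(de_genes) - set(ids))
    if missing:
        raise ValueError(f"DE genes absent from the universe: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    n_draw = len(de_genes)
    if not cfg.with_replacement and n_draw > len(universe):
        raise ValueError("cannot draw more genes than the universe holds without replacement")
    flags = universe["has_peak"].to_numpy(dtype=bool)
    observed = int(flags[ids.get_indexer(de_genes)].sum())

    rng = np.random.default_rng(cfg.seed)
    n_universe = len(flags)
    null_counts = np.empty(cfg.n_iter, dtype=np.int64)
    for i in range(cfg.n_iter):
        draw = rng.choice(n_universe, size=n_draw, replace=cfg.with_replacement)
        null_counts[i] = flags[draw].sum()
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=1))
    r = int((null_counts >= observed).sum())
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=observed / null_mean if null_mean > 0 else np.inf,
        empirical_p=(r + 1) / (cfg.n_iter + 1),
        null_counts=null_counts,
    )


def screen_persistent_tfs(
    lfc_table: pd.DataFrame,
    tf_ids: set[str],
    *,
    fdr: float = 0.1,
    min_lfc: float = 0.0,
) -> pd.DataFrame:
    """Transcription factors induced early and still high later.

    Keeps genes significantly upregulated at 6 h (fdr < threshold and
    log2FC > min_lfc) whose log2FC at 48 h also exceeds ``min_lfc``, restricted
    to the supplied TF identifiers, sorted by 48 h log2FC descending.
    """
    required = {"gene_id", "log2fc_6h", "fdr_6h", "log2fc_48h"}
    missing = required - set(lfc_table.columns)
    if missing:
        raise ValueError(f"lfc table missing columns {sorted(missing)}")
    keep = (
        (lfc_table["fdr_6h"] < fdr)
        & (lfc_table["log2fc_6h"] > min_lfc)
        & (lfc_table["log2fc_48h"] > min_lfc)
        & lfc_table["gene_id"].isin(tf_ids)
    )
    return (
        lfc_table.loc[keep]
        .sort_values("log2fc_48h", ascending=False)
        .reset_index(drop=True)
    )
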