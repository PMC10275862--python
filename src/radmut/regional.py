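"""Regional mutation-rate enrichment over covariate bins.

Mutation counts per genomic bin (replication-timing quantile, expression
level, chromatin mark) are modelled with a negative-binomial GLM with log
link; sequence-composition exposure enters as a log-opportunity offset, so
bin-level coefficients are log rate ratios relative to a reference level.
Treatment effects on the regional gradient are tested through
treatment x level interaction terms in a joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BinCounts:
    bins: pd.DataFrame       # chrom, start, end (0-based half-open), covariate_level, count
    unassigned: int = 0

    @property
    def total(self) -> int:
        return int(self.bins["count"].sum()) + self.unassigned


def count_mutations_per_bin(mutations: pd.DataFrame, bins: pd.DataFrame) -> BinCounts:
    """Assign 1-based mutation positions to 0-based half-open bins.

    Bins must be non-overlapping within each chromosome; mutations outside
    every bin are tallied as unassigned.
    """
    bins = bins.reset_index(drop=True).copy()
    counts = np.zeros(len(bins), dtype=int)
    unassigned = 0
    grouped = {c: g.sort_values("start") for c, g in bins.groupby("chrom")}
    for g in grouped.values():
        starts, ends = g["start"].values, g["end"].values
        if np.any(ends <= starts):
            raise ValueError("bin end must exceed start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("overlapping bins within a chromosome")
    for chrom, muts in mutations.groupby("chrom"):
        g = grouped.get(chrom)
        pos0 = muts["pos"].values.astype(int) - 1  # to 0-based
        if g is None:
            unassigned += len(pos0)
            continue
        starts, ends = g["start"].values, g["end"].values
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        unassigned += int((~ok).sum())
        hit_rows = g.index.values[idx[ok]]
        np.add.at(counts, hit_rows, 1)
    bins["count"] = counts
    return BinCounts(bins=bins, unassigned=unassigned)


def trinucleotide_composition(genome, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin counts of the 32 pyrimidine-centred trinucleotides."""
    from .catalogs import BASES, revcomp

    tris = sorted(
        {t if t[1] in "CT" else revcomp(t)
         for t in (a + b + c for a in BASES for b in BASES for c in BASES)}
    )
    rows = []
    for _, b in bins.iterrows():
        seq = genome.fetch(b["chrom"], int(b["start"]) + 1, int(b["end"]))
        counts = dict.fromkeys(tris, 0)
        for i in range(len(seq) - 2):
            t = seq[i : i + 3]
            if "N" in t:
                continue
            t = t if t[1] in "CT" else revcomp(t)
            counts[t] += 1
        rows.append(counts)
    return pd.DataFrame(rows, index=bins.index)


def context_offset(composition: pd.DataFrame, tri_rates: pd.Series | None = None) -> np.ndarray:
    """Log-opportunity offset per bin from trinucleotide composition.

    ``tri_rates`` are genome-wide per-trinucleotide mutation rates; when
    omitted every context is weighted equally, i.e. the offset reduces to
    log at-risk site count.
    """
    if tri_rates is None:
        opp = composition.sum(axis=1).values.astype(float)
    else:
        rates = tri_rates.reindex(composition.columns).fillna(0.0).values
        opp = composition.values @ rates
    if np.any(opp <= 0):
        raise ValueError("non-positive opportunity in some bin")
    return np.log(opp)


@dataclass
class RegressionFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    dispersion: float          # NB2 alpha: Var = mu + alpha mu^2
    converged: bool
    method: str = "mle"
    model: object = field(default=None, repr=False)


def _nb_fit(formula: str, data: pd.DataFrame, offset: np.ndarray | None):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.negativebinomial(formula, data=data, offset=offset).fit(
                disp=0, maxiter=200
            )
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.isfinite(res.params).all():
            alpha = float(res.params.get("alpha", np.nan))
            params = res.params.drop(labels=["alpha"], errors="ignore")
            return RegressionFit(
                params=params,
                bse=res.bse.drop(labels=["alpha"], errors="ignore"),
                pvalues=res.pvalues.drop(labels=["alpha"], errors="ignore"),
                dispersion=alpha,
                converged=True,
                method="mle",
                model=res,
            )
    except Exception:
        pass
    # fallback: moment estimate of alpha from a Poisson fit, then NB GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = smf.glm(formula, data=data, family=sm.families.Poisson(),
                       offset=offset).fit()
        mu = pois.fittedvalues.values
        y = pois.model.endog
        num = float(np.sum((y - mu) ** 2 - mu))
        den = float(np.sum(mu**2))
        alpha = max(num / den, 1e-8) if den > 0 else 1e-8
        res = smf.glm(formula, data=data,
                      family=sm.families.NegativeBinomial(alpha=alpha),
                      offset=offset).fit()
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        dispersion=alpha,
        converged=True,
        method="moments",
        model=res,
    )


def fit_nb_regression(
    bins: pd.DataFrame,
    level_col: str = "covariate_level",
    count_col: str = "count",
    offset: np.ndarray | None = None,
    extra_terms: list[str] | None = None,
) -> RegressionFit:
    """Negative-binomial regression of bin counts on the covariate level.

    Level coefficients (treatment-style coding) are log rate ratios
    relative to the reference level; pass a log-opportunity ``offset`` to
    control for sequence composition, or add context terms via
    ``extra_terms``.
    """
    if bins[level_col].nunique() < 2:
        raise ValueError("need at least 2 covariate levels")
    counts = bins[count_col].values
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    level_totals = bins.groupby(level_col)[count_col].sum()
    if (level_totals == 0).any() and len(bins) < 50:
        raise ValueError(
            f"all counts zero at level(s) {list(level_totals[level_totals == 0].index)}; "
            "fit would be degenerate"
        )
    terms = [f"C({level_col})"] + (extra_terms or [])
    formula = f"{count_col} ~ " + " + ".join(terms)
    return _nb_fit(formula, bins, offset)


def compare_treatment_slopes(
    bins: pd.DataFrame,
    treatment_col: str = "treatment",
    level_col: str = "covariate_level",
    count_col: str = "count",
    offset: np.ndarray | None = None,
    reference: str | None = None,
) -> RegressionFit:
    """Joint NB model with treatment x (numeric) level interaction.

    The level enters as an ordinal trend so each interaction coefficient is
    the change of the regional log-rate slope for a treatment relative to
    the reference group, with its Wald p-value.
    """
    groups = bins[treatment_col].unique()
    if len(groups) < 2:
        raise ValueError("treatment x level interaction needs >= 2 treatment groups")
    data = bins.copy()
    levels = sorted(data[level_col].unique())
    data["_level_num"] = data[level_col].map({lv: i for i, lv in enumerate(levels)})
    ref = reference or sorted(groups)[0]
    formula = (
        f"{count_col} ~ C({treatment_col}, Treatment(reference='{ref}')) * _level_num"
    )
    fit = _nb_fit(formula, data, offset)
    return fit


def interaction_pvalues(fit: RegressionFit) -> pd.Series:
    """Wald p-values of the treatment x level interaction terms."""
    mask = fit.pvalues.index.str.contains(":_level_num")
    return fit.pvalues[mask]


def simulate_bin_counts(
    n_bins: int,
    rate_ratio: float = 2.0,
    base_rate: float = 20.0,
    dispersion: float = 0.05,
    n_levels: int = 2,
    seed: int = 0,
    treatments: list[str] | None = None,
    slope_by_treatment: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic bin counts with a known regional gradient.

    Levels run from early (reference) to late; the late/early rate ratio is
    ``rate_ratio`` interpolated geometrically across levels. Counts are
    gamma-Poisson (NB2 with the given dispersion). With ``treatments``,
    bins are replicated per treatment and ``slope_by_treatment`` scales the
    per-level log gradient of each group.
    """
    rng = np.random.default_rng(seed)
    rows = []
    treatments = treatments or ["pooled"]
    slope_by_treatment = slope_by_treatment or {t: 1.0 for t in treatments}
    log_step = np.log(rate_ratio) / max(n_levels - 1, 1)
    for t in treatments:
        scale = slope_by_treatment.get(t, 1.0)
        for i in range(n_bins):
            level = i % n_levels
            mu = base_rate * np.exp(scale * log_step * level)
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            else:
                lam = mu
            rows.append(
                {
                    "chrom": "chr1",
                    "start": i * 1000,
                    "end": (i + 1) * 1000,
                    "covariate_level": f"L{level}",
                    "treatment": t,
                    "count": int(rng.poisson(lam)),
                }
            )
    return pd.DataFrame(rows)
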