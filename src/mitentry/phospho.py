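"""Phosphosite statistics for the 2x2 factorial TMT design.

The experiment compares four cell states collected as three biological
replicates across three TMT sixplex labeling batches (each batch carries
one replicate of every state plus pooled reference channels):

========  ===========  ===========
state     treatment    fraction
========  ===========  ===========
G2        DMSO         attached
Prometa   DMSO         suspended
ProPro    BI2536       attached
Polo      BI2536       suspended
========  ===========  ===========

``treatment`` is +/- the PLK1 inhibitor BI 2536 and ``fraction``
(attached vs suspended after shake-off) separates pre- from post-NEBD
cells.  The pipeline is: remove contaminant/reverse/poorly-localised
sites; require >= 70% valid intensities per labeling batch; impute
missing (not-at-random, low-abundance) values from a down-shifted
narrowed Gaussian per channel; normalise by Tukey median polish per
batch; fit a per-site least-squares model of the four group means;
shrink residual variances with an empirical-Bayes scaled-F prior
(moderated t); and test contrasts with Benjamini-Hochberg adjustment.

The interaction contrast

    [BI2536.attached - BI2536.suspended] - [DMSO.attached - DMSO.suspended]

defines phosphosites specific to prolonged prophase: responsive to PLK1
inhibition only before NEBD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUPS",
    "PAIRWISE_CONTRASTS",
    "PhosphositeTable",
    "FactorialFit",
    "filter_sites",
    "valid_value_filter",
    "impute_mnar",
    "reference_align",
    "median_polish",
    "median_polish_normalize",
    "fit_factorial",
    "moderate_variances",
    "interaction_contrast",
    "pairwise_contrasts",
    "bh_adjust",
    "classify_hits",
    "run_pipeline",
]

#: group -> (treatment, fraction)
GROUPS = {
    "G2": ("DMSO", "attached"),
    "Prometa": ("DMSO", "suspended"),
    "ProPro": ("BI2536", "attached"),
    "Polo": ("BI2536", "suspended"),
}

#: the four edges of the 2x2 square, as (name, positive group, negative group)
PAIRWISE_CONTRASTS = (
    ("Prometa_vs_G2", "Prometa", "G2"),
    ("Polo_vs_ProPro", "Polo", "ProPro"),
    ("ProPro_vs_G2", "ProPro", "G2"),
    ("Polo_vs_Prometa", "Polo", "Prometa"),
)


@dataclass
class PhosphositeTable:
    """Site-level metadata plus a log2 intensity matrix with missingness.

    ``sites``: one row per (site, multiplicity) quantification unit, indexed
    like ``intensities``; expected columns include ``protein``, ``gene``,
    ``residue``, ``position``, ``multiplicity``, ``localization_prob``,
    ``contaminant``, ``reverse``.

    ``intensities``: sites x samples, log2 scale, NaN = missing.

    ``samples``: one row per intensity column with ``group``, ``treatment``,
    ``fraction``, ``replicate``, ``batch`` and ``is_reference``.
    """

    sites: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = True

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.intensities.index):
            raise ValueError("sites and intensities must share an index")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples annotation lacks columns: {sorted(missing)}")
        if self.sites.index.has_duplicates:
            raise ValueError("duplicate (site, multiplicity) keys")
        if "localization_prob" in self.sites:
            probs = self.sites["localization_prob"].to_numpy(float)
            ok = np.isnan(probs) | ((probs >= 0) & (probs <= 1))
            if not ok.all():
                raise ValueError("localization probabilities must lie in [0, 1]")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = observed)."""
        return self.intensities.notna()

    def copy(self) -> "PhosphositeTable":
        return PhosphositeTable(
            self.sites.copy(), self.intensities.copy(), self.samples.copy(), self.log2
        )

    def sample_columns(self, batch=None, include_reference: bool = True) -> list:
        sel = pd.Series(True, index=self.samples.index)
        if batch is not None:
            sel &= self.samples["batch"] == batch
        if not include_reference:
            sel &= ~self.samples["is_reference"].astype(bool)
        cols = self.samples.index[sel]
        return [c for c in self.intensities.columns if c in set(cols)]


def filter_sites(table: PhosphositeTable, loc_prob_min: float = 0.75) -> PhosphositeTable:
    """Drop contaminant and reverse-hit rows and sites with localization
    probability below ``loc_prob_min`` (sites exactly at the cutoff stay)."""
    s = table.sites
    keep = pd.Series(True, index=s.index)
    if "contaminant" in s:
        keep &= ~s["contaminant"].astype(bool)
    if "reverse" in s:
        keep &= ~s["reverse"].astype(bool)
    if "localization_prob" in s:
        keep &= s["localization_prob"].astype(float) >= loc_prob_min
    return PhosphositeTable(
        s.loc[keep].copy(), table.intensities.loc[keep].copy(),
        table.samples.copy(), table.log2,
    )


def valid_value_filter(
    table: PhosphositeTable, min_valid_fraction: float = 0.70
) -> PhosphositeTable:
    """Apply the per-batch valid-value rule.

    Within each labeling batch, a site observed in fewer than
    ``min_valid_fraction`` of that batch's non-reference channels is
    considered not quantified in that batch: all its values there
    (reference channels included) are blanked.  Sites quantified in no
    batch are dropped.
    """
    out = table.copy()
    batches = sorted(out.samples["batch"].unique())
    quantified_somewhere = pd.Series(False, index=out.intensities.index)
    for b in batches:
        cols = out.sample_columns(batch=b, include_reference=False)
        all_cols = out.sample_columns(batch=b, include_reference=True)
        if not cols:
            continue
        frac = out.intensities[cols].notna().mean(axis=1)
        bad = frac < min_valid_fraction
        out.intensities.loc[bad, all_cols] = np.nan
        quantified_somewhere |= ~bad
    keep = quantified_somewhere
    return PhosphositeTable(
        out.sites.loc[keep].copy(), out.intensities.loc[keep].copy(),
        out.samples.copy(), out.log2,
    )


def impute_mnar(
    table: PhosphositeTable,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> PhosphositeTable:
    """Down-shifted Gaussian imputation of missing log2 intensities.

    Missing values are assumed missing-not-at-random (low abundance below
    the detection limit), so each TMT channel/replicate column's gaps are
    filled with draws from ``Normal(mean_obs - downshift*sd_obs,
    (width*sd_obs)^2)`` where ``mean_obs``/``sd_obs`` are that column's
    observed statistics — the Perseus convention with the width and
    downshift expressed in column-SD units.
    """
    if not table.log2:
        raise ValueError("imputation expects log2-transformed intensities")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    too_few = [
        c for c in out.intensities.columns if out.intensities[c].notna().sum() < 2
    ]
    if too_few:
        raise ValueError(f"cannot impute columns with <2 observed values: {too_few}")
    for c in out.intensities.columns:
        col = out.intensities[c]
        gaps = col.isna()
        if not gaps.any():
            continue
        mu, sd = col.mean(), col.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, int(gaps.sum()))
        out.intensities.loc[gaps, c] = draws
    return out


def reference_align(table: PhosphositeTable, drop_reference: bool = True) -> PhosphositeTable:
    """Internal-reference scaling across batches.

    The pooled samples carried in each batch's reference channels estimate
    a common profile; subtracting, per batch and site, the mean reference
    value centres every batch on that profile.  Optional (and switchable
    off) because the operational use of the pooled channels is a design
    choice of this pipeline.
    """
    out = table.copy()
    for b in sorted(out.samples["batch"].unique()):
        ref_cols = [
            c for c in out.sample_columns(batch=b)
            if bool(out.samples.loc[c, "is_reference"])
        ]
        if not ref_cols:
            continue
        profile = out.intensities[ref_cols].mean(axis=1)
        cols = out.sample_columns(batch=b)
        out.intensities[cols] = out.intensities[cols].sub(profile, axis=0)
    if drop_reference:
        keep = [c for c in out.intensities.columns
                if not bool(out.samples.loc[c, "is_reference"])]
        out = PhosphositeTable(
            out.sites, out.intensities[keep], out.samples.loc[keep], out.log2
        )
    return out


def median_polish(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> dict:
    """Tukey median polish of a two-way table.

    Alternating row/column median sweeps until the largest absolute median
    removed in a full sweep drops below ``tol``.  Returns the additive
    decomposition ``overall + row + col + residual`` plus convergence info.
    """
    resid = np.asarray(matrix, dtype=float).copy()
    if resid.ndim != 2:
        raise ValueError("median polish needs a 2-D matrix")
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col

        delta = max(np.max(np.abs(rmed), initial=0.0),
                    np.max(np.abs(cmed), initial=0.0))
        if delta < tol:
            converged = True
            break
    return {
        "overall": overall, "row": row, "col": col, "residual": resid,
        "converged": converged, "n_iter": it,
    }


def median_polish_normalize(
    table: PhosphositeTable, tol: float = 1e-6, max_iter: int = 100
) -> tuple[PhosphositeTable, pd.Series]:
    """Remove sample (column) effects by median polish, batch by batch.

    Normalised value = original - column effect; row effects (site
    baselines) are retained, since this is a normalisation rather than a
    full decomposition.  Returns the normalised table and the per-sample
    column effects.  Requires a complete (post-imputation) matrix.
    """
    out = table.copy()
    effects = pd.Series(0.0, index=out.intensities.columns)
    overalls: dict = {}
    polished: dict = {}
    for b in sorted(out.samples["batch"].unique()):
        cols = out.sample_columns(batch=b)
        if not cols:
            continue
        sub = out.intensities[cols]
        rows = sub.notna().all(axis=1)
        if not rows.all():
            raise ValueError(
                "median-polish normalisation needs a complete matrix per batch; "
                "impute (or drop) missing values first"
            )
        polished[b] = (cols, sub.to_numpy(),
                       median_polish(sub.to_numpy(), tol=tol, max_iter=max_iter))
        overalls[b] = polished[b][2]["overall"]
    # Batch-level offsets live in each batch's overall term; centring the
    # overalls and folding them into the column effects aligns batches while
    # preserving the grand intensity level (for a single batch this reduces
    # to plain column-effect removal).
    grand = float(np.mean(list(overalls.values()))) if overalls else 0.0
    for b, (cols, arr, mp) in polished.items():
        col_eff = mp["col"] + (overalls[b] - grand)
        out.intensities[cols] = arr - col_eff[None, :]
        effects[cols] = col_eff
    return out, effects


@dataclass
class FactorialFit:
    """Per-site least-squares group means with (optionally moderated)
    residual variances for the 2x2 factorial design.

    ``coefficients`` holds one column per group mean; ``sigma2`` the
    residual variance s^2 with ``df`` residual degrees of freedom per site.
    After :func:`moderate_variances`, ``s2_post`` holds the shrunken
    variance ``(d0*s0^2 + d*s^2)/(d0 + d)`` and ``df_total = df + d0``.
    """

    coefficients: pd.DataFrame  # sites x groups
    sigma2: pd.Series
    df: pd.Series
    n_per_group: pd.DataFrame  # sites x groups
    s2_post: pd.Series | None = None
    d0: float | None = None
    s0_2: float | None = None

    @property
    def moderated(self) -> bool:
        return self.s2_post is not None


def fit_factorial(table: PhosphositeTable) -> FactorialFit:
    """Per-site least squares on the four treatment x fraction cells.

    With a full-rank cell-means design this is the per-group sample mean;
    the residual variance pools within-group scatter with
    ``df = n - #groups``.  Reference channels are excluded.
    """
    cols = [c for c in table.intensities.columns
            if not bool(table.samples.loc[c, "is_reference"])]
    groups = table.samples.loc[cols, "group"]
    present = [g for g in GROUPS if g in set(groups)]
    if len(present) < len(GROUPS):
        missing = sorted(set(GROUPS) - set(present))
        raise ValueError(f"design is rank deficient; missing groups: {missing}")
    counts = groups.value_counts()
    if (counts < 2).any():
        few = sorted(counts[counts < 2].index)
        raise ValueError(f"need >= 2 replicates per group, too few in: {few}")

    X = table.intensities[cols]
    coef = pd.DataFrame(index=X.index, columns=list(GROUPS), dtype=float)
    npg = pd.DataFrame(index=X.index, columns=list(GROUPS), dtype=float)
    rss = pd.Series(0.0, index=X.index)
    n_obs = pd.Series(0, index=X.index)
    for g in GROUPS:
        gcols = [c for c in cols if groups[c] == g]
        sub = X[gcols]
        coef[g] = sub.mean(axis=1)
        npg[g] = sub.notna().sum(axis=1)
        rss += ((sub.sub(coef[g], axis=0)) ** 2).sum(axis=1)
        n_obs += sub.notna().sum(axis=1)
    df = (n_obs - len(GROUPS)).astype(float)
    sigma2 = rss.where(df > 0) / df.where(df > 0)
    return FactorialFit(coefficients=coef, sigma2=sigma2, df=df, n_per_group=npg)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = (tri - y) / polygamma(2, x)
        x -= step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(fit: FactorialFit, min_sites: int = 10) -> FactorialFit:
    """Empirical-Bayes shrinkage of per-site residual variances.

    The sample variances are modelled as scaled F draws around a prior
    ``s0^2`` with ``d0`` prior degrees of freedom; hyperparameters are
    estimated by matching the mean and variance of ``log s^2`` through
    digamma/trigamma moments.  If the observed variances carry no excess
    spread (e.g. all equal), the prior dominates: ``d0 = inf`` and every
    posterior variance equals ``s0^2``.
    """
    ok = fit.sigma2.notna() & (fit.sigma2 > 0) & (fit.df > 0)
    if int(ok.sum()) < min_sites:
        raise ValueError(
            f"need >= {min_sites} sites with positive variance to estimate the prior"
        )
    s2 = fit.sigma2[ok].to_numpy(float)
    d = fit.df[ok].to_numpy(float)
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi^2 sampling noise: degenerate prior,
        # pooled to the arithmetic mean variance
        d0 = np.inf
        s0_2 = float(np.mean(s2))

    if np.isinf(d0):
        s2_post = pd.Series(s0_2, index=fit.sigma2.index)
    else:
        s2_post = (d0 * s0_2 + fit.df * fit.sigma2.fillna(0.0)) / (d0 + fit.df)
    return replace(fit, s2_post=s2_post, d0=float(d0), s0_2=s0_2)


def _contrast_table(
    fit: FactorialFit, weights: dict[str, float], sites: pd.DataFrame | None
) -> pd.DataFrame:
    if not fit.moderated:
        fit = moderate_variances(fit)
    lfc = sum(w * fit.coefficients[g] for g, w in weights.items())
    unscaled = sum(w ** 2 / fit.n_per_group[g] for g, w in weights.items())
    se = np.sqrt(fit.s2_post * unscaled)
    t = lfc / se
    df_total = fit.df + (0.0 if np.isinf(fit.d0) else fit.d0)
    if np.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    out = pd.DataFrame({
        "log2fc": lfc, "t": t, "p": p, "adj_p": bh_adjust(p),
    }, index=fit.coefficients.index)
    if sites is not None:
        meta_cols = [c for c in ("protein", "gene", "residue", "position") if c in sites]
        out = sites[meta_cols].join(out, how="right")
    return out


def interaction_contrast(
    fit: FactorialFit, sites: pd.DataFrame | None = None
) -> pd.DataFrame:
    """The prolonged-prophase interaction:
    (ProPro - Polo) - (G2 - Prometa), i.e.
    [BI2536.attached - BI2536.suspended] - [DMSO.attached - DMSO.suspended]."""
    weights = {"ProPro": 1.0, "Polo": -1.0, "G2": -1.0, "Prometa": 1.0}
    return _contrast_table(fit, weights, sites)


def pairwise_contrasts(
    fit: FactorialFit, sites: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """The four pairwise comparisons along the edges of the 2x2 square."""
    out = {}
    for name, pos, neg in PAIRWISE_CONTRASTS:
        out[name] = _contrast_table(fit, {pos: 1.0, neg: -1.0}, sites)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_hits(
    contrast_table: pd.DataFrame, p_cut: float = 0.05, lfc_cut: float = 0.5
) -> pd.Series:
    """Label sites ``up`` / ``down`` / ``ns``.

    Significance requires adjusted p < ``p_cut`` and |log2FC| > ``lfc_cut``;
    with ``lfc_cut=0`` the classification is by sign alone, the rule used
    for the Up/Down counts of the four pairwise comparisons (the volcano
    classification uses the default 0.5 cutoff).
    """
    sig = (contrast_table["adj_p"] < p_cut) & (
        contrast_table["log2fc"].abs() > lfc_cut
    )
    out = pd.Series("ns", index=contrast_table.index, dtype=object)
    out[sig & (contrast_table["log2fc"] > 0)] = "up"
    out[sig & (contrast_table["log2fc"] < 0)] = "down"
    return out


def run_pipeline(
    table: PhosphositeTable,
    loc_prob_min: float = 0.75,
    min_valid_fraction: float = 0.70,
    width: float = 0.3,
    downshift: float = 1.8,
    use_reference: bool = False,
    seed: int = 0,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> dict:
    """Filter -> impute -> normalise -> fit -> moderate -> test, end to end.

    Returns a dict with the processed table, the moderated fit, the
    interaction contrast (with ``class`` labels) and the four pairwise
    contrast tables.
    """
    t = filter_sites(table, loc_prob_min)
    t = valid_value_filter(t, min_valid_fraction)
    t = impute_mnar(t, width=width, downshift=downshift, seed=seed)
    if use_reference:
        t = reference_align(t)
    t, col_effects = median_polish_normalize(t)
    fit = moderate_variances(fit_factorial(t))
    inter = interaction_contrast(fit, t.sites)
    inter["class"] = classify_hits(inter, p_cut=p_cut, lfc_cut=lfc_cut)
    pairs = {}
    for name, tab in pairwise_contrasts(fit, t.sites).items():
        tab = tab.copy()
        tab["class"] = classify_hits(tab, p_cut=p_cut, lfc_cut=0.0)
        pairs[name] = tab
    return {
        "table": t,
        "column_effects": col_effects,
        "fit": fit,
        "interaction": inter,
        "pairwise": pairs,
    }
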