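"""Three complementary transcript-protein association analyses.

(a) Fold-change correlation: OLS of protein L2fc on transcript L2fc across
    genes, per contrast.
(b) Pooled abundance model: a linear mixed-effects model of ln RPKM on
    ln Mol% over all matched (gene, replicate) pairs, with a random
    intercept and random slope per replicate (the turbidostat unit), plus
    a pooled Pearson R^2 on the same filtered pairs. Very low abundance
    transcripts (RPKM < 2.0 by default) are excluded.
(c) Per-gene regressions: one OLS fit per gene across its matched samples,
    summarised by the R^2 distribution (median over all genes and over the
    significantly differentially expressed subset) and a census of slope
    signs.

Protein and transcript samples are matched by experimental unit: pairs are
formed only for replicates present in both assays (at the proteome day), so
transcript samples without a TMT channel drop out of (b) and (c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_RPKM_MIN = 2.0


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series,
                 library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``library_sizes`` defaults to the column sums of ``counts``.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    len_kb = lengths.to_numpy(float) / 1e3
    mill = library_sizes.to_numpy(float) / 1e6
    return counts / (len_kb[:, None] * mill[None, :])


def l2fc_correlation(protein_l2fc: pd.Series,
                     transcript_l2fc: pd.Series) -> tuple[float, float, int]:
    """OLS of protein L2fc on transcript L2fc over genes shared by both
    series (unmatched features are dropped and counted in the log).
    Returns ``(R^2, slope, n)``."""
    merged = pd.concat({"t": transcript_l2fc, "p": protein_l2fc},
                       axis=1, join="inner").dropna()
    merged = merged[np.isfinite(merged).all(axis=1)]
    n_dropped = max(len(protein_l2fc), len(transcript_l2fc)) - len(merged)
    if n_dropped:
        logger.info("l2fc_correlation: %d unmatched/non-finite features dropped",
                    n_dropped)
    if len(merged) < 3:
        raise ValueError("need >= 3 matched finite pairs")
    fit = stats.linregress(merged["t"], merged["p"])
    return float(fit.rvalue ** 2), float(fit.slope), len(merged)


def matched_abundance_pairs(molpct: pd.DataFrame, rpkm: pd.DataFrame,
                            design: pd.DataFrame,
                            annotations: pd.DataFrame | None = None,
                            rpkm_min: float = DEFAULT_RPKM_MIN,
                            day: int | None = None) -> pd.DataFrame:
    """Long table of (gene, replicate, log_molpct, log_rpkm) pairs.

    Samples are matched by replicate unit across assays; when a protein
    accession differs from the transcript gene id an ``annotations`` table
    (accession, gene_id) provides the link. Natural logs; pairs with
    RPKM < ``rpkm_min`` or nonpositive Mol% are excluded (counts logged).
    """
    prot = design[(design["assay"] == "protein")
                  & design["sample"].isin(molpct.columns)]
    tran = design[(design["assay"] == "transcript")
                  & design["sample"].isin(rpkm.columns)]
    if day is not None:
        tran = tran[tran["day"] == day]
    else:
        # default: transcript samples from the proteome day(s)
        prot_days = set(prot["day"])
        tran = tran[tran["day"].isin(prot_days)]
    t_by_unit = dict(zip(tran["replicate"], tran["sample"]))

    if annotations is not None:
        acc_to_gene = dict(zip(annotations["accession"], annotations["gene_id"]))
    else:
        acc_to_gene = {a: a for a in molpct.index}

    frames = []
    n_low, n_zero = 0, 0
    for _, row in prot.iterrows():
        unit = row["replicate"]
        tsample = t_by_unit.get(unit)
        if tsample is None:
            continue
        x = molpct[row["sample"]]
        genes = x.index.map(acc_to_gene)
        y = rpkm[tsample].reindex(genes)
        df = pd.DataFrame({"gene": genes, "accession": x.index,
                           "replicate": unit,
                           "molpct": x.to_numpy(float),
                           "rpkm": y.to_numpy(float)}).dropna()
        low = df["rpkm"] < rpkm_min
        zero = df["molpct"] <= 0
        n_low += int(low.sum())
        n_zero += int(zero.sum())
        df = df[~low & ~zero]
        frames.append(df)
    if not frames:
        raise ValueError("no matched protein/transcript samples")
    pairs = pd.concat(frames, ignore_index=True)
    pairs["log_molpct"] = np.log(pairs["molpct"])
    pairs["log_rpkm"] = np.log(pairs["rpkm"])
    logger.info("matched pairs: %d kept, %d below RPKM %.3g, %d zero Mol%%",
                len(pairs), n_low, rpkm_min, n_zero)
    return pairs


@dataclass
class MixedModelFit:
    """Pooled mixed-effects fit of ln RPKM on ln Mol%."""
    intercept: float
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    random_intercept_var: float
    random_slope_var: float
    residual_var: float
    pooled_r2: float
    n_pairs: int
    n_replicates: int
    converged: bool

    def summary(self) -> str:
        lo, hi = self.slope_ci
        return (
            "Pooled mixed-effects model: log_rpkm ~ log_molpct, "
            "random ~1 + log_molpct | replicate\n"
            f"  fixed intercept      {self.intercept: .4f}\n"
            f"  fixed slope          {self.slope: .4f}  "
            f"(SE {self.slope_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}])\n"
            f"  var(random intercept) {self.random_intercept_var:.4f}\n"
            f"  var(random slope)     {self.random_slope_var:.4f}\n"
            f"  var(residual)         {self.residual_var:.4f}\n"
            f"  pooled Pearson R2     {self.pooled_r2:.4f}\n"
            f"  n pairs {self.n_pairs}, replicates {self.n_replicates}, "
            f"converged {self.converged}")


def fit_pooled_mixed_model(pairs: pd.DataFrame,
                           reml: bool = True) -> MixedModelFit:
    """Fit the random-intercept + random-slope model to a matched-pairs
    table (from :func:`matched_abundance_pairs` or the generator's
    ``simulate_replicate_abundance``)."""
    n_rep = pairs["replicate"].nunique()
    if n_rep < 2:
        raise ValueError("mixed model is degenerate with < 2 replicates; "
                         "use pooled OLS instead")
    model = smf.mixedlm("log_rpkm ~ log_molpct", pairs,
                        groups=pairs["replicate"], re_formula="~log_molpct")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fit = model.fit(reml=reml, method=["lbfgs", "powell"])
    # t-based CI with between-replicate degrees of freedom: the normal-
    # quantile Wald interval undercovers when the slope varies over only a
    # handful of replicate units
    df = max(n_rep - 2, 1)
    tcrit = stats.t.ppf(0.975, df)
    slope, se = float(fit.params["log_molpct"]), float(fit.bse["log_molpct"])
    ci = (slope - tcrit * se, slope + tcrit * se)
    r = np.corrcoef(pairs["log_molpct"], pairs["log_rpkm"])[0, 1]
    cov_re = np.asarray(fit.cov_re)
    return MixedModelFit(
        intercept=float(fit.params["Intercept"]),
        slope=float(fit.params["log_molpct"]),
        slope_se=float(fit.bse["log_molpct"]),
        slope_ci=ci,
        random_intercept_var=float(cov_re[0, 0]),
        random_slope_var=float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        residual_var=float(fit.scale),
        pooled_r2=float(r ** 2),
        n_pairs=len(pairs),
        n_replicates=int(n_rep),
        converged=bool(fit.converged),
    )


def per_gene_regressions(pairs: pd.DataFrame,
                         de_table: pd.DataFrame | None = None,
                         min_points: int = 3):
    """Per-gene OLS of ln RPKM (response) on ln Mol% (predictor).

    Returns ``(fits, summary, exclusions)``: a table of GenePairFit rows
    (gene, slope, intercept, r2, n_points, significant), a summary dict
    with the two medians, and an exclusion table with reason codes
    (``too_few_points`` / ``constant_predictor``).
    """
    sig_map = {}
    if de_table is not None:
        sig_map = dict(zip(de_table["feature"], de_table["significant"]))
    rows, excluded = [], []
    for gene, sub in pairs.groupby("gene", sort=True):
        acc = sub["accession"].iloc[0] if "accession" in sub else gene
        if len(sub) < min_points:
            excluded.append((gene, "too_few_points", len(sub)))
            continue
        x = sub["log_molpct"].to_numpy(float)
        y = sub["log_rpkm"].to_numpy(float)
        if np.ptp(x) == 0:
            excluded.append((gene, "constant_predictor", len(sub)))
            continue
        fit = stats.linregress(x, y)
        r2 = fit.rvalue ** 2 if np.ptp(y) > 0 else 0.0
        rows.append({"gene": gene, "accession": acc,
                     "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "r2": float(r2), "n_points": len(sub),
                     "significant": bool(sig_map.get(acc, False))})
    fits = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded,
                              columns=["gene", "reason", "n_points"])
    summary = {
        "n_models": len(fits),
        "n_excluded": len(exclusions),
        "median_r2_all": float(fits["r2"].median()) if len(fits) else float("nan"),
        "median_r2_significant": (
            float(fits.loc[fits["significant"], "r2"].median())
            if len(fits) and fits["significant"].any() else float("nan")),
    }
    return fits, summary, exclusions


def slope_sign_census(fits: pd.DataFrame,
                      only_significant: bool = False) -> tuple[float, float, int]:
    """Fractions of positive and negative per-gene slopes.

    Genes with slope exactly 0 or undefined are excluded from the census.
    Returns ``(frac_positive, frac_negative, n)`` with the fractions
    summing to 1.
    """
    sub = fits
    if only_significant:
        sub = sub[sub["significant"]]
    slopes = sub["slope"].to_numpy(float)
    slopes = slopes[np.isfinite(slopes) & (slopes != 0)]
    n = len(slopes)
    if n == 0:
        raise ValueError("no fits with a defined nonzero slope")
    frac_pos = float((slopes > 0).sum()) / n
    return frac_pos, 1.0 - frac_pos, n


def correlation_report(fc_results: dict, mixed: MixedModelFit,
                       summary: dict, census_all: tuple,
                       census_sig: tuple | None = None) -> pd.DataFrame:
    """Flatten the three analyses into a (method, statistic, value, n) table."""
    rows = []
    for contrast, (r2, slope, n) in fc_results.items():
        rows.append(("l2fc_correlation", f"r2[{contrast}]", r2, n))
        rows.append(("l2fc_correlation", f"slope[{contrast}]", slope, n))
    rows += [
        ("pooled_mixed_model", "fixed_slope", mixed.slope, mixed.n_pairs),
        ("pooled_mixed_model", "fixed_intercept", mixed.intercept, mixed.n_pairs),
        ("pooled_mixed_model", "pooled_pearson_r2", mixed.pooled_r2, mixed.n_pairs),
        ("pooled_mixed_model", "random_slope_var", mixed.random_slope_var,
         mixed.n_replicates),
        ("per_gene_regression", "n_models", summary["n_models"],
         summary["n_models"]),
        ("per_gene_regression", "median_r2_all", summary["median_r2_all"],
         summary["n_models"]),
        ("per_gene_regression", "median_r2_significant",
         summary["median_r2_significant"], summary["n_models"]),
        ("slope_sign_census", "frac_positive_all", census_all[0], census_all[2]),
        ("slope_sign_census", "frac_negative_all", census_all[1], census_all[2]),
    ]
    if census_sig is not None:
        rows.append(("slope_sign_census", "frac_positive_significant",
                     census_sig[0], census_sig[2]))
        rows.append(("slope_sign_census", "frac_negative_significant",
                     census_sig[1], census_sig[2]))
    return pd.DataFrame(rows, columns=["method", "statistic", "value", "n"])
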