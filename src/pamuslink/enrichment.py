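"""Gene-set statistics on per-feature log2 fold changes.

Three complementary tests, each BH-adjusted across terms:

* ``logistic_gsea`` — logistic regression of set membership (0/1) on L2fc;
  the fitted slope is the log-odds ratio (LOR). LOR > 0 means the set is
  over-represented among upregulated features, LOR < 0 among downregulated
  ones. Default significance: q < 0.01.
* ``fisher_enrichment`` — classic (hierarchy-free) one-sided Fisher /
  hypergeometric test of a 2x2 table (in-set x in-direction), run
  separately for up- and downregulated feature lists. Default q < 0.05.
* ``set_level_test`` — a set-level two-sample Welch t statistic comparing
  member vs non-member L2fc (a GAGE-style test fed per-gene fold changes).
  Unidirectional mode reports a one-sided p for each direction;
  bidirectional mode tests |L2fc| two-sided. Sets need *more than*
  ``min_members`` annotated members (strict). Default q < 0.05.

Sets are intersected with the quantified universe first (features without
an L2fc are removed), then size-filtered; GO terms with fewer than five
annotated genes are pruned by default for the logistic and Fisher tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: term_id <tab> description <tab> member ids...."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = (parts[1], [m for m in parts[2:] if m])
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            name, members = sets[term]
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")


def sets_from_annotations(annotations: pd.DataFrame, column: str,
                          id_column: str = "accession") -> dict:
    """Build gene sets from a ;-separated annotation column (go_terms or
    ko_terms)."""
    members: dict[str, list] = {}
    for fid, terms in zip(annotations[id_column], annotations[column]):
        if not isinstance(terms, str) or not terms:
            continue
        for term in terms.split(";"):
            term = term.strip()
            if term:
                members.setdefault(term, []).append(fid)
    return {t: (t, sorted(set(m))) for t, m in members.items()}


def _prepare_sets(sets: dict, universe, min_members: int,
                  strict: bool = False) -> dict[str, list[str]]:
    """Intersect sets with the universe and size-filter (``>= min_members``
    by default, ``> min_members`` when strict)."""
    uni = set(universe)
    out = {}
    for term, payload in sets.items():
        members = payload[1] if isinstance(payload, tuple) else payload
        inter = sorted(set(members) & uni)
        keep = len(inter) > min_members if strict else len(inter) >= min_members
        if keep:
            out[term] = inter
    return out


def logistic_gsea(l2fc: pd.Series, sets: dict, fdr_cutoff: float = 0.01,
                  min_members: int = 5) -> pd.DataFrame:
    """Logistic gene-set model: membership ~ L2fc per term.

    On complete separation the term is reported with an infinite-LOR flag
    and a likelihood-ratio bound p-value instead of crashing.
    """
    l2fc = l2fc.dropna()
    l2fc = l2fc[np.isfinite(l2fc)]
    prepared = _prepare_sets(sets, l2fc.index, min_members)
    x = sm.add_constant(l2fc.to_numpy(float))
    rows = []
    for term in sorted(prepared):
        members = prepared[term]
        y = l2fc.index.isin(members).astype(float)
        lor, p, separated = _fit_logistic(y, x)
        rows.append({"term": term, "method": "logistic",
                     "statistic": lor, "p_raw": p,
                     "direction": "up" if lor > 0 else "down",
                     "n_members_tested": len(members),
                     "separated": separated})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p_raw"])
        result["significant"] = result["q"] < fdr_cutoff
    return result


def _fit_logistic(y: np.ndarray, x: np.ndarray):
    """Return (LOR, p, separated_flag) for membership ~ L2fc."""
    import warnings as _w

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # convergence chatter on hard fits
            _w.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        lor = float(fit.params[1])
        p = float(fit.pvalues[1])
        # huge |slope| with huge SE is numerically separated
        if not np.isfinite(p) or abs(lor) > 50:
            raise np.linalg.LinAlgError("separation")
        return lor, p, False
    except Exception:
        # complete/quasi-complete separation: sign from the mean L2fc
        # difference, p bounded by the LR statistic at the null
        n1 = y.sum()
        mu1 = (x[:, 1] * y).sum() / max(n1, 1)
        mu0 = (x[:, 1] * (1 - y)).sum() / max(len(y) - n1, 1)
        sign = 1.0 if mu1 >= mu0 else -1.0
        pbar = y.mean()
        llnull = len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar))
        p = float(stats.chi2.sf(-2.0 * llnull, df=1))
        return sign * np.inf, p, True


def fisher_enrichment(de_labels: pd.Series, sets: dict, direction: str,
                      alpha: float = 0.05, min_members: int = 5) -> pd.DataFrame:
    """One-sided Fisher / hypergeometric over-representation test.

    ``de_labels``: per-feature labels in {"up", "down", "ns"};
    ``direction``: which label defines the interesting class. p =
    P(overlap >= observed) under the hypergeometric null.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    universe = de_labels.index
    N = len(universe)
    hits = set(de_labels.index[de_labels == direction])
    K = len(hits)
    prepared = _prepare_sets(sets, universe, min_members)
    rows = []
    for term in sorted(prepared):
        members = prepared[term]
        n = len(members)
        k = len(hits.intersection(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        odds_num = k * (N - K - n + k)
        odds_den = (n - k) * (K - k)
        odds = odds_num / odds_den if odds_den > 0 else np.inf
        rows.append({"term": term, "method": "fisher",
                     "statistic": odds, "p_raw": p, "direction": direction,
                     "n_members_tested": n, "n_overlap": k})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p_raw"])
        result["significant"] = result["q"] < alpha
    return result


def set_level_test(l2fc: pd.Series, sets: dict, min_members: int = 5,
                   q_cutoff: float = 0.05,
                   mode: str = "unidirectional") -> pd.DataFrame:
    """Set-level Welch t test of member vs non-member L2fc.

    Only sets with more than ``min_members`` annotated members (strict
    inequality) are tested. ``mode="unidirectional"`` emits one record per
    direction per term with one-sided p-values, BH-adjusted within each
    direction; ``mode="bidirectional"`` tests |L2fc| two-sided.
    """
    if mode not in {"unidirectional", "bidirectional"}:
        raise ValueError("mode must be 'unidirectional' or 'bidirectional'")
    l2fc = l2fc.dropna()
    l2fc = l2fc[np.isfinite(l2fc)]
    prepared = _prepare_sets(sets, l2fc.index, min_members, strict=True)
    values = l2fc if mode == "unidirectional" else l2fc.abs()
    rows = []
    for term in sorted(prepared):
        members = prepared[term]
        mask = values.index.isin(members)
        a = values[mask].to_numpy(float)
        b = values[~mask].to_numpy(float)
        if len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            t = 0.0
            p_greater = p_less = p_two = 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t = float(res.statistic)
            p_two = float(res.pvalue)
            p_greater = p_two / 2 if t > 0 else 1 - p_two / 2
            p_less = p_two / 2 if t < 0 else 1 - p_two / 2
        if mode == "unidirectional":
            rows.append({"term": term, "method": "set_t", "statistic": t,
                         "p_raw": p_greater, "direction": "up",
                         "n_members_tested": len(members)})
            rows.append({"term": term, "method": "set_t", "statistic": t,
                         "p_raw": p_less, "direction": "down",
                         "n_members_tested": len(members)})
        else:
            rows.append({"term": term, "method": "set_t_bidir", "statistic": t,
                         "p_raw": p_two,
                         "direction": "perturbed" if t > 0 else "stable",
                         "n_members_tested": len(members)})
    result = pd.DataFrame(rows)
    if len(result):
        qs = np.empty(len(result))
        for direction, idx in result.groupby("direction").groups.items():
            qs[result.index.get_indexer(idx)] = bh_adjust(
                result.loc[idx, "p_raw"])
        result["q"] = qs
        result["significant"] = result["q"] < q_cutoff
    return result
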