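"""emPAI / PAMUS protein quantification from TMT reporter-ion intensities.

The workflow turns a table of peptide-spectrum matches (PSMs), each carrying
ten reporter-ion intensities, into per-sample molar protein abundances:

1. identifications are filtered to a target protein/peptide FDR and a
   minimum number of unique peptides per protein;
2. reporter intensities are corrected for TMT isotope impurities by solving
   the channel-mixing linear system;
3. each protein's emPAI (``10^PAI - 1`` with ``PAI = observed/observable``
   tryptic peptides) estimates its molar amount in the pooled, multiplexed
   sample;
4. the emPAI is partitioned over the ten channels in proportion to the
   protein's summed reporter intensities (the PAMUS step), and the channel
   shares are normalised to Mol% — each sample's protein amounts sum to 100.

Reporter responses differ between peptides, so raw intensities are only
semi-quantitative across proteins; emPAI anchors the between-protein scale
while the reporter ratios carry the between-sample signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass
from pyteomics import parser as _pt_parser

logger = logging.getLogger(__name__)

#: TMT 10-plex reporter labels, low to high m/z.
TMT10_LABELS = ("126", "127N", "127C", "128N", "128C",
                "129N", "129C", "130N", "130C", "131")

#: PSM-table column names for the reporter channels.
CHANNEL_COLUMNS = tuple(f"ch{lbl}" for lbl in TMT10_LABELS)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Cleave after K or R unless the next residue is proline.
_TRYPSIN_RULE = r"[KR](?!P)"

#: Default observable-peptide mass window (monoisotopic Da), a typical
#: Orbitrap precursor acquisition range.
DEFAULT_MASS_WINDOW = (500.0, 5000.0)


def digest_protein(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P.

    With ``m`` missed cleavages every concatenation of up to ``m + 1``
    adjacent fragments is returned; duplicate sequences are collapsed.
    Peptides are returned sorted for determinism.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    peptides = _pt_parser.cleave(sequence, _TRYPSIN_RULE,
                                 missed_cleavages=missed_cleavages)
    return sorted(peptides)


def peptide_mass(peptide: str) -> float:
    """Monoisotopic mass of an unmodified peptide (residues + water), Da."""
    return float(_pt_mass.fast_mass(peptide))


def count_observable_peptides(peptides,
                              mass_window=DEFAULT_MASS_WINDOW) -> int:
    """Count distinct peptides whose monoisotopic mass is inside the window."""
    lo, hi = mass_window
    return sum(lo <= peptide_mass(p) <= hi for p in set(peptides))


def compute_empai(n_observed: int, n_observable: int) -> tuple[float, float]:
    """Return ``(PAI, emPAI)`` with PAI = observed/observable, emPAI = 10^PAI - 1."""
    if n_observable < 1:
        raise ValueError("protein has no observable peptides (n_observable = 0)")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    pai = n_observed / n_observable
    return pai, 10.0 ** pai - 1.0


def correct_isotope_impurities(raw, impurity) -> np.ndarray:
    """Undo TMT isotope-impurity mixing of reporter intensities.

    ``impurity[i, j]`` is the fraction of label *j*'s signal that appears in
    observed channel *i*, so observed = impurity @ true per PSM. The
    correction solves that linear system; small negative solutions (noise)
    are clamped to zero with a logged warning.
    """
    raw = np.asarray(raw, dtype=float)
    impurity = np.asarray(impurity, dtype=float)
    if impurity.ndim != 2 or impurity.shape[0] != impurity.shape[1]:
        raise ValueError("impurity matrix must be square")
    squeeze = raw.ndim == 1
    mat = np.atleast_2d(raw)
    if mat.shape[1] != impurity.shape[0]:
        raise ValueError("intensity width does not match impurity matrix size")
    try:
        corrected = np.linalg.solve(impurity, mat.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"impurity matrix is singular: {exc}") from exc
    n_neg = int((corrected < 0).sum())
    if n_neg:
        logger.warning("isotope correction produced %d negative intensities; "
                       "clamped to 0", n_neg)
        corrected = np.clip(corrected, 0.0, None)
    return corrected[0] if squeeze else corrected


def _fdr_threshold_keep(probs: np.ndarray, fdr: float) -> np.ndarray:
    """Boolean keep-mask: largest high-confidence prefix whose estimated
    FDR (mean posterior error, ``1 - prob``) stays at or below ``fdr``."""
    order = np.argsort(-probs, kind="stable")
    pep = 1.0 - probs[order]
    est_fdr = np.cumsum(pep) / np.arange(1, len(pep) + 1)
    ok = est_fdr <= fdr + 1e-12
    keep = np.zeros(len(probs), dtype=bool)
    if ok.any():
        last = np.max(np.nonzero(ok)[0])
        keep[order[: last + 1]] = True
    return keep


def filter_identifications(psms: pd.DataFrame,
                           protein_fdr: float = 0.03,
                           peptide_fdr: float = 0.03,
                           min_unique_peptides: int = 2) -> pd.DataFrame:
    """Apply identification confidence filters to a PSM table.

    Expects ``peptide_prob`` and ``protein_prob`` columns (posterior
    probabilities, as a search-engine/post-processor would supply). PSMs are
    thresholded so the estimated peptide FDR is at most ``peptide_fdr``;
    proteins likewise at ``protein_fdr``; proteins with fewer than
    ``min_unique_peptides`` distinct peptide sequences are then removed.
    """
    n0 = len(psms)
    out = psms
    if "peptide_prob" in out.columns:
        keep = _fdr_threshold_keep(out["peptide_prob"].to_numpy(float), peptide_fdr)
        out = out.loc[keep]
    if "protein_prob" in out.columns and len(out):
        prot_prob = out.groupby("accession")["protein_prob"].max()
        keep_prot = _fdr_threshold_keep(prot_prob.to_numpy(float), protein_fdr)
        kept_accessions = set(prot_prob.index[keep_prot])
        out = out[out["accession"].isin(kept_accessions)]
    if len(out):
        n_unique = out.groupby("accession")["peptide"].nunique()
        good = set(n_unique.index[n_unique >= min_unique_peptides])
        out = out[out["accession"].isin(good)]
    logger.info("identification filter: %d -> %d PSMs, %d proteins retained",
                n0, len(out), out["accession"].nunique() if len(out) else 0)
    return out.reset_index(drop=True)


def _resolve_shared_peptides(psms: pd.DataFrame) -> pd.DataFrame:
    """Assign peptides observed under several accessions to a single protein.

    Winner = the accession with the most unique peptides (ties broken
    lexicographically), a parsimony rule in the spirit of cluster-style
    protein reporting.
    """
    pep_acc = psms[["peptide", "accession"]].drop_duplicates()
    multi = pep_acc.groupby("peptide")["accession"].nunique()
    shared = set(multi.index[multi > 1])
    if not shared:
        return psms
    n_unique = psms.groupby("accession")["peptide"].nunique()
    remap = {}
    for pep in shared:
        cands = sorted(pep_acc.loc[pep_acc["peptide"] == pep, "accession"])
        # winner: most unique peptides, ties -> lexicographically smallest
        best = max(n_unique.get(a, 0) for a in cands)
        remap[pep] = min(a for a in cands if n_unique.get(a, 0) == best)
    out = psms.copy()
    mask = out["peptide"].isin(shared)
    out.loc[mask, "accession"] = out.loc[mask, "peptide"].map(remap)
    return out


@dataclass
class QuantOptions:
    """Knobs for :func:`pamus_quantify`."""
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
    missed_cleavages: int = 0
    aggregate: str = "sum"  # PSM -> protein intensity aggregation: sum | mean


def pamus_quantify(psms: pd.DataFrame,
                   sequences: dict[str, str],
                   design: pd.DataFrame,
                   options: QuantOptions | None = None) -> pd.DataFrame:
    """PAMUS quantification: emPAI partitioned over channels, then Mol%.

    Parameters
    ----------
    psms : filtered PSM table with ``peptide``, ``accession`` and the ten
        ``ch*`` reporter columns (impurity-corrected).
    sequences : accession -> protein sequence, for the observable-peptide
        denominator of PAI.
    design : sample sheet with ``sample`` and ``tmt_label`` columns mapping
        each labelled channel to a sample.

    Returns a table with one row per quantified protein: observed/observable
    peptide counts, PAI, emPAI, per-channel emPAI shares (``share_ch*``) and
    per-sample Mol% (``molpct_<sample>``). Per sample the Mol% column sums
    to 100.
    """
    options = options or QuantOptions()
    missing = [a for a in psms["accession"].unique() if a not in sequences]
    if missing:
        raise KeyError(f"PSM accessions absent from protein DB: {missing[:5]}")
    psms = _resolve_shared_peptides(psms)

    chan_cols = [c for c in CHANNEL_COLUMNS if c in psms.columns]
    if not chan_cols:
        raise ValueError("PSM table has no reporter channel columns")

    agg = psms.groupby("accession").agg(
        **{c: (c, options.aggregate) for c in chan_cols})
    n_obs = psms.groupby("accession")["peptide"].nunique()

    rows = []
    for acc in sorted(agg.index):
        peptides = digest_protein(sequences[acc], options.missed_cleavages)
        n_able = count_observable_peptides(peptides, options.mass_window)
        if n_able == 0:
            logger.warning("protein %s has no observable peptides; dropped", acc)
            continue
        intens = agg.loc[acc, chan_cols].to_numpy(float)
        total = intens.sum()
        if total <= 0:
            logger.warning("protein %s has zero intensity in all channels; "
                           "dropped", acc)
            continue
        pai, empai = compute_empai(int(n_obs[acc]), n_able)
        shares = empai * intens / total
        row = {"accession": acc, "n_observed": int(n_obs[acc]),
               "n_observable": n_able, "pai": pai, "empai": empai}
        row.update({f"share_{c}": s for c, s in zip(chan_cols, shares)})
        rows.append(row)
    if not rows:
        raise ValueError("no quantifiable proteins after filtering")
    quant = pd.DataFrame(rows)

    share_cols = [f"share_{c}" for c in chan_cols]
    share_totals = quant[share_cols].sum(axis=0)
    label_to_sample = channel_sample_map(design)
    for c in chan_cols:
        label = c[2:]
        sample = label_to_sample.get(label)
        if sample is None:
            continue
        denom = share_totals[f"share_{c}"]
        quant[f"molpct_{sample}"] = (
            100.0 * quant[f"share_{c}"] / denom if denom > 0 else 0.0)
    return quant


def channel_sample_map(design: pd.DataFrame) -> dict[str, str]:
    """Map TMT label -> sample id from the design sheet (labelled rows only)."""
    lab = design.dropna(subset=["tmt_label"])
    lab = lab[lab["tmt_label"].astype(str) != ""]
    return dict(zip(lab["tmt_label"].astype(str), lab["sample"].astype(str)))


def molpct_matrix(quant: pd.DataFrame) -> pd.DataFrame:
    """Extract the Mol% block as a protein x sample matrix."""
    cols = [c for c in quant.columns if c.startswith("molpct_")]
    out = quant.set_index("accession")[cols]
    out.columns = [c[len("molpct_"):] for c in cols]
    return out
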