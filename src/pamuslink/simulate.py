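"""Synthetic paired TMT-proteome / RNA-seq nutrient-deprivation study.

The generator emulates the statistical structure the downstream analysis
assumes, with recorded ground truth:

* a protein database (FASTA) of random tryptic-digestible sequences with
  compartment, GO and KEGG-orthology annotations;
* a 10-plex TMT design — 4 control, 4 nitrogen-deprived (N-), 2
  phosphorus-deprived (P-) channels at day 3 — alongside 12 transcript
  samples per day (4 per group, days 3 and 5), reproducing the label
  shortage of a 12-turbidostat experiment with only 10 TMT labels;
* per-gene treatment effects on the log2 scale: a strong, dense N- contrast
  and a weak, sparse P- contrast, with day-5 effects an escalated version of
  day-3 effects in the same direction;
* gene-level transcript->protein coupling: protein log2 deviations equal
  kappa_g times the mRNA log2 deviation plus noise, with a configured
  mixture of positively coupled, negatively coupled and uncoupled genes;
* compartment-specific protein shifts (default: plastid down under N-);
* PSM-level reporter intensities = true per-channel abundance x fixed
  lognormal peptide response factor x lognormal noise, mixed by a TMT
  isotope-impurity matrix; plus decoy/low-confidence PSMs so identification
  filters have work to do;
* negative-binomial transcript counts at a configured depth and dispersion.

All randomness flows from ``SimConfig.seed`` through per-stage child
generators, so each artefact is bit-reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tmt_quant import CHANNEL_COLUMNS, TMT10_LABELS

# Amino-acid alphabet with roughly natural frequencies; K and R are common
# enough that tryptic digestion of a 150+ residue protein yields many
# peptides.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
                     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

GROUPS = ("C", "N-", "P-")

_COMPARTMENTS = ("plastid", "mitochondrion", "endoplasmic reticulum",
                 "membrane", "cytoplasm", "nucleus", "unannotated")
_COMPARTMENT_PROBS = (0.24, 0.12, 0.08, 0.16, 0.22, 0.10, 0.08)

# Location strings as a UniProt "Subcellular location" field would carry
# them; downstream mapping must synonymise and roll these up.
_LOCATION_STRINGS = {
    "plastid": ("Plastid, chloroplast stroma", "Plastid, chloroplast thylakoid membrane",
                "Chloroplast"),
    "mitochondrion": ("Mitochondrion", "Mitochondrion inner membrane",
                      "Mitochondrion matrix"),
    "endoplasmic reticulum": ("Endoplasmic reticulum",
                              "Endoplasmic reticulum membrane"),
    "membrane": ("Membrane", "Cell membrane", "Plasma membrane"),
    "cytoplasm": ("Cytoplasm", "Cytoplasm, cytosol"),
    "nucleus": ("Nucleus", "Nucleus, nucleolus"),
    "unannotated": ("",),
}


def default_impurity_matrix(n_channels: int = 10, leak: float = 0.03) -> np.ndarray:
    """A TMT-style isotope impurity matrix: each label leaks ``leak`` of its
    signal into each adjacent channel (columns sum to <= 1)."""
    m = np.eye(n_channels) * (1 - 2 * leak)
    for j in range(n_channels):
        if j > 0:
            m[j - 1, j] += leak
        if j + 1 < n_channels:
            m[j + 1, j] += leak
        m[j, j] += leak * ((j == 0) + (j == n_channels - 1))
    return m


@dataclass
class SimConfig:
    """Generator configuration. Defaults mirror the study design: 4/4/2
    proteome channels for C/N-/P-, 4 transcript replicates per group on
    days 3 and 5, a dense strong N- contrast and a sparse weak P- contrast,
    and a 79/21 positive/negative transcript->protein coupling mixture."""

    n_genes: int = 1000
    n_replicates_per_group: dict = field(
        default_factory=lambda: {"C": 4, "N-": 4, "P-": 2})
    n_transcript_replicates: int = 4
    days: tuple = (3, 5)
    proteome_day: int = 3

    frac_affected_N: float = 0.40
    frac_affected_P: float = 0.03
    effect_sd_N: float = 0.8
    effect_sd_P: float = 0.4
    day5_escalation: float = 1.6

    coupling_mix: tuple = (0.79, 0.21, 0.0)   # (positive, negative, null)
    coupling_strength: float = 1.0
    bio_sd: float = 0.15          # per-replicate biological fluctuation, log2
    protein_noise_sd: float = 0.10  # residual protein noise, log2
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    protein_baseline_slope: float = 0.5   # log2-protein vs log2-mRNA, cross-gene
    protein_baseline_sd: float = 1.0

    compartment_shift: dict = field(
        default_factory=lambda: {"N-": {"plastid": -0.4}})

    reporter_noise_cv: float = 0.20
    isotope_impurity_matrix: np.ndarray | None = None
    peptide_response_sd: float = 0.5    # lognormal sigma of response factors
    frac_single_peptide: float = 0.10
    # Observed peptides ~ Binomial(n_observable, PAI target); the target PAI
    # rises with standardised log protein abundance, the empirical relation
    # emPAI quantification rests on.
    pai_base: float = 0.40
    pai_abundance_slope: float = 0.15
    # Deterministic-PAI mode rounds the observed-peptide count to the PAI
    # target instead of drawing it, for noiseless rank-order checks.
    deterministic_pai: bool = False
    mean_extra_psms: float = 1.0        # PSMs per peptide ~ 1 + Poisson(mean)
    frac_decoy: float = 0.03
    missingness: float = 0.0            # P(channel intensity zeroed) per protein
    # Planted enriched GO sets (one up, one down) assembled from the most
    # strongly shifted proteins of the N- contrast; 0 disables planting.
    planted_set_size: int = 35

    seq_length_range: tuple = (150, 600)
    count_depth: float = 3e6
    dispersion: float = 0.05
    n_go_terms: int = 40
    n_ko_terms: int = 15
    mean_go_per_gene: float = 2.0
    mean_ko_per_gene: float = 0.8

    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("frac_affected_N", "frac_affected_P", "frac_single_peptide",
                     "frac_decoy", "missingness"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.coupling_mix) - 1.0) > 1e-9:
            raise ValueError("coupling_mix must sum to 1")
        if any(f < 0 for f in self.coupling_mix):
            raise ValueError("coupling_mix fractions must be nonnegative")
        if self.count_depth <= 0:
            raise ValueError("count_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        m = self.impurity()
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("impurity matrix must be square")
        if (m < 0).any():
            raise ValueError("impurity matrix entries must be nonnegative")

    def impurity(self) -> np.ndarray:
        if self.isotope_impurity_matrix is None:
            return default_impurity_matrix(len(TMT10_LABELS))
        return np.asarray(self.isotope_impurity_matrix, dtype=float)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped generator so each artefact is independently seeded."""
        return np.random.default_rng([int(self.seed), stage])


_STAGE_TRUTH, _STAGE_DB, _STAGE_PSM, _STAGE_COUNTS = 1, 2, 3, 4


@dataclass
class GroundTruth:
    """Everything the generator decided, for recovery tests.

    ``genes``: one row per gene (baselines, per-contrast effects, coupling
    coefficient kappa, true DE labels, compartment, GO/KO memberships, slope
    sign). ``protein_log2``: true per-channel log2 protein abundance
    (gene x proteome sample). ``mrna_log2``: expected per-sample log2 mRNA
    abundance (gene x transcript sample). ``sequences`` is filled by
    :func:`generate_protein_db`.
    """
    genes: pd.DataFrame
    protein_log2: pd.DataFrame
    mrna_log2: pd.DataFrame
    design: pd.DataFrame
    planted_sets: pd.DataFrame | None = None
    sequences: dict | None = None


def simulate_design(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet: proteome channels (with TMT labels) at the proteome day
    plus transcript samples for every group/replicate/day."""
    rows = []
    label_iter = iter(TMT10_LABELS)
    for group in GROUPS:
        for r in range(1, cfg.n_replicates_per_group[group] + 1):
            rows.append({"sample": f"P_{group}{r}", "assay": "protein",
                         "group": group, "day": cfg.proteome_day,
                         "replicate": f"{group}{r}",
                         "tmt_label": next(label_iter)})
    for day in cfg.days:
        for group in GROUPS:
            for r in range(1, cfg.n_transcript_replicates + 1):
                rows.append({"sample": f"T_{group}{r}_d{day}",
                             "assay": "transcript", "group": group,
                             "day": day, "replicate": f"{group}{r}",
                             "tmt_label": ""})
    return pd.DataFrame(rows)


def generate_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw gene-level truth and true per-sample abundances."""
    cfg.validate()
    rng = cfg.rng(_STAGE_TRUTH)
    n = cfg.n_genes
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n)]
    accessions = [f"NGS{i + 1:05d}" for i in range(n)]

    base_m = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    base_p = (cfg.protein_baseline_slope * (base_m - cfg.baseline_log2_mean)
              + rng.normal(0.0, cfg.protein_baseline_sd, n))

    affected_N = rng.random(n) < cfg.frac_affected_N
    affected_P = rng.random(n) < cfg.frac_affected_P
    delta_N = np.where(affected_N, rng.normal(0.0, cfg.effect_sd_N, n), 0.0)
    delta_P = np.where(affected_P, rng.normal(0.0, cfg.effect_sd_P, n), 0.0)

    kappa_cat = rng.choice(3, size=n, p=list(cfg.coupling_mix))
    kappa = np.where(kappa_cat == 0, cfg.coupling_strength,
                     np.where(kappa_cat == 1, -cfg.coupling_strength, 0.0))

    compartment = rng.choice(_COMPARTMENTS, size=n, p=_COMPARTMENT_PROBS)
    loc_strings = [
        _LOCATION_STRINGS[c][rng.integers(len(_LOCATION_STRINGS[c]))]
        for c in compartment]

    go_pool = [f"GO:{7000000 + i}" for i in range(cfg.n_go_terms)]
    ko_pool = [f"KO:{10000 + i}" for i in range(cfg.n_ko_terms)]
    go_terms, ko_terms = [], []
    for _ in range(n):
        k_go = min(rng.poisson(cfg.mean_go_per_gene), cfg.n_go_terms)
        k_ko = min(rng.poisson(cfg.mean_ko_per_gene), cfg.n_ko_terms)
        go_terms.append(";".join(sorted(
            rng.choice(go_pool, size=k_go, replace=False))) if k_go else "")
        ko_terms.append(";".join(sorted(
            rng.choice(ko_pool, size=k_ko, replace=False))) if k_ko else "")

    seq_len = rng.integers(cfg.seq_length_range[0],
                           cfg.seq_length_range[1] + 1, n)
    gene_len = 3 * seq_len + rng.integers(200, 1501, n)

    genes = pd.DataFrame({
        "gene_id": gene_ids, "accession": accessions,
        "baseline_log2_mrna": base_m, "baseline_log2_protein": base_p,
        "affected_N": affected_N, "affected_P": affected_P,
        "delta_N_day3": delta_N, "delta_N_day5": cfg.day5_escalation * delta_N,
        "delta_P_day3": delta_P, "delta_P_day5": cfg.day5_escalation * delta_P,
        "kappa": kappa, "slope_sign": np.sign(kappa).astype(int),
        "compartment": compartment, "subcellular_location": loc_strings,
        "go_terms": go_terms, "ko_terms": ko_terms,
        "protein_length": seq_len, "gene_length": gene_len,
    })

    design = simulate_design(cfg)
    delta = {("N-", 3): genes["delta_N_day3"].to_numpy(),
             ("N-", 5): genes["delta_N_day5"].to_numpy(),
             ("P-", 3): genes["delta_P_day3"].to_numpy(),
             ("P-", 5): genes["delta_P_day5"].to_numpy()}
    zero = np.zeros(n)

    # Per-replicate biological fluctuation, shared between the two assays of
    # the same turbidostat unit so transcript and protein co-vary.
    units = sorted(design["replicate"].unique())
    bio = {u: rng.normal(0.0, cfg.bio_sd, n) for u in units}

    shift_cfg = cfg.compartment_shift or {}

    mrna_cols, prot_cols = {}, {}
    for _, row in design.iterrows():
        d = delta.get((row["group"], row["day"]), zero)
        b = bio[row["replicate"]]
        if row["assay"] == "transcript":
            mrna_cols[row["sample"]] = base_m + d + b
        else:
            shift = np.zeros(n)
            for comp, s in shift_cfg.get(row["group"], {}).items():
                shift += np.where(compartment == comp, s, 0.0)
            noise = rng.normal(0.0, cfg.protein_noise_sd, n)
            prot_cols[row["sample"]] = base_p + kappa * (d + b) + shift + noise

    mrna_log2 = pd.DataFrame(mrna_cols, index=gene_ids)
    protein_log2 = pd.DataFrame(prot_cols, index=accessions)

    # True DE labels: affected genes with a non-zero effect on the relevant
    # scale (transcript: delta itself; protein: kappa*delta or a shift).
    genes["de_true_N"] = affected_N & (delta_N != 0)
    genes["de_true_P"] = affected_P & (delta_P != 0)

    # Planted enriched sets: the most strongly shifted proteins of the N-
    # contrast form one downregulated and one upregulated GO term, so
    # enrichment recovery can be checked against known direction.
    planted = None
    if cfg.planted_set_size > 0:
        shift_vec = np.zeros(n)
        for comp, s in shift_cfg.get("N-", {}).items():
            shift_vec += np.where(compartment == comp, s, 0.0)
        prot_eff = kappa * delta_N + shift_vec
        k = int(cfg.planted_set_size)
        # sample members across the whole shifted tail (not just the most
        # extreme proteins) so set membership overlaps the background L2fc
        # distribution the way real pathways do
        down_pool = np.flatnonzero(prot_eff < -0.3)
        up_pool = np.flatnonzero(prot_eff > 0.3)
        down_idx = (rng.choice(down_pool, size=k, replace=False)
                    if len(down_pool) > k else down_pool)
        up_idx = (rng.choice(up_pool, size=k, replace=False)
                  if len(up_pool) > k else up_pool)
        rows = []
        for term, direction, idx in (("GO:7999901", "down", down_idx),
                                     ("GO:7999902", "up", up_idx)):
            if len(idx) < 3:
                continue
            members = sorted(accessions[i] for i in idx)
            rows.append({"term": term, "direction": direction,
                         "members": ";".join(members)})
            for i in idx:
                cur = genes.at[i, "go_terms"]
                genes.at[i, "go_terms"] = (cur + ";" + term) if cur else term
        planted = pd.DataFrame(rows, columns=["term", "direction", "members"])

    return GroundTruth(genes=genes, protein_log2=protein_log2,
                       mrna_log2=mrna_log2, design=design,
                       planted_sets=planted)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    seq = rng.choice(_AA, size=length, p=_AA_FREQ)
    return "".join(seq)


def generate_protein_db(cfg: SimConfig, truth: GroundTruth | None = None):
    """Generate protein sequences and the annotation table.

    Returns ``(truth, records, annotations)`` where ``records`` is a list of
    Bio.SeqRecord and ``annotations`` has columns (accession, gene_id,
    go_terms, ko_terms, subcellular_location). Sequences are stored on the
    truth object for PSM simulation.
    """
    if truth is None:
        truth = generate_ground_truth(cfg)
    rng = cfg.rng(_STAGE_DB)
    records, sequences = [], {}
    for _, g in truth.genes.iterrows():
        seq = _random_sequence(rng, int(g["protein_length"]))
        sequences[g["accession"]] = seq
        records.append(SeqRecord(Seq(seq), id=g["accession"],
                                 description=g["gene_id"]))
    annotations = truth.genes[["accession", "gene_id", "go_terms",
                               "ko_terms", "subcellular_location"]].copy()
    truth.sequences = sequences
    return truth, records, annotations


def simulate_psm_table(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate the PSM table with 10 reporter intensities per row.

    Intensities are true per-channel protein abundance (linear scale) x a
    fixed lognormal per-peptide response factor x lognormal noise at the
    configured CV, then mixed by the isotope impurity matrix. A configured
    fraction of proteins yields only one unique peptide (so identification
    filters are exercised) and a fraction of decoy PSMs with low confidence
    is appended.
    """
    if truth.sequences is None:
        raise ValueError("protein DB not generated; call generate_protein_db first")
    from .tmt_quant import DEFAULT_MASS_WINDOW, digest_protein, peptide_mass

    impurity = cfg.impurity()
    if impurity.shape[0] != impurity.shape[1]:
        raise ValueError("impurity matrix must be square")
    rng = cfg.rng(_STAGE_PSM)
    sigma = np.sqrt(np.log1p(cfg.reporter_noise_cv ** 2))

    log2_ab = truth.protein_log2.to_numpy()
    abundance = np.power(2.0, log2_ab)            # gene x channel, linear
    mean_log2 = log2_ab.mean(axis=1)
    z = ((mean_log2 - mean_log2.mean()) / (mean_log2.std() or 1.0))

    lo, hi = DEFAULT_MASS_WINDOW
    rows = []
    spectrum = 0
    for gi, acc in enumerate(truth.protein_log2.index):
        # observed peptides come from the observable mass window, and their
        # number tracks abundance: that is the PAI-abundance relation the
        # emPAI estimate downstream relies on
        peptides = [p for p in digest_protein(truth.sequences[acc], 0)
                    if lo <= peptide_mass(p) <= hi]
        if not peptides:
            continue
        target_pai = float(np.clip(
            cfg.pai_base + cfg.pai_abundance_slope * z[gi], 0.02, 0.98))
        if cfg.deterministic_pai:
            n_pep = max(1, round(len(peptides) * target_pai))
        elif rng.random() < cfg.frac_single_peptide:
            n_pep = 1
        else:
            n_pep = max(1, rng.binomial(len(peptides), target_pai))
        chosen = rng.choice(len(peptides), size=n_pep, replace=False)
        true_ab = abundance[gi].copy()
        if cfg.missingness > 0:
            true_ab = np.where(rng.random(len(true_ab)) < cfg.missingness,
                               0.0, true_ab)
        for pi in chosen:
            response = float(rng.lognormal(0.0, cfg.peptide_response_sd))
            n_psm = 1 + rng.poisson(cfg.mean_extra_psms)
            for _ in range(n_psm):
                if sigma > 0:
                    noise = rng.lognormal(0.0, sigma, len(true_ab))
                else:
                    noise = 1.0
                intens = impurity @ (1e4 * true_ab * response * noise)
                spectrum += 1
                rows.append((f"spec_{spectrum:07d}", peptides[pi], acc,
                             float(rng.uniform(0.97, 1.0)),
                             float(rng.uniform(0.98, 1.0)), False, *intens))

    n_decoy = int(round(cfg.frac_decoy * len(rows)))
    for d in range(n_decoy):
        spectrum += 1
        pep = _random_sequence(rng, int(rng.integers(8, 20)))
        intens = rng.lognormal(6.0, 1.0, impurity.shape[0])
        rows.append((f"spec_{spectrum:07d}", pep, f"DECOY_{d + 1:04d}",
                     float(rng.uniform(0.0, 0.6)),
                     float(rng.uniform(0.0, 0.5)), True, *intens))

    cols = (["spectrum_id", "peptide", "accession", "peptide_prob",
             "protein_prob", "is_decoy"] + list(CHANNEL_COLUMNS))
    return pd.DataFrame(rows, columns=cols)


def simulate_counts(cfg: SimConfig, truth: GroundTruth):
    """Negative-binomial transcript counts.

    Per sample, expected counts are the depth split over genes in proportion
    to (2^log2-abundance x gene length); dispersion alpha gives variance
    mu + alpha mu^2 (alpha = 0 is exactly Poisson).

    Returns ``(counts, gene_lengths)``.
    """
    if cfg.count_depth <= 0:
        raise ValueError("count_depth must be positive")
    rng = cfg.rng(_STAGE_COUNTS)
    lengths = truth.genes.set_index("gene_id")["gene_length"].astype(int)
    weights = np.power(2.0, truth.mrna_log2.to_numpy()) * lengths.to_numpy()[:, None]
    mu = cfg.count_depth * weights / weights.sum(axis=0, keepdims=True)
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu * cfg.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    counts = pd.DataFrame(counts, index=truth.mrna_log2.index,
                          columns=truth.mrna_log2.columns)
    return counts, lengths


def simulate_replicate_abundance(n_genes: int, n_replicates: int,
                                 slope: float = 0.8, intercept: float = 2.0,
                                 slope_sd: float = 0.1,
                                 intercept_sd: float = 0.2,
                                 noise_sd: float = 0.5,
                                 x_mean: float = 0.0, x_sd: float = 1.5,
                                 seed: int = 0) -> pd.DataFrame:
    """Direct generator for the pooled mixed-model data-generating process.

    Per replicate r: y_gr = (intercept + u_r) + (slope + v_r) * x_gr + eps,
    with u ~ N(0, intercept_sd^2), v ~ N(0, slope_sd^2). ``x`` plays the
    role of log Mol%, ``y`` of log RPKM. Used for parameter-recovery tests
    of the mixed-effects fit.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for r in range(1, n_replicates + 1):
        u = rng.normal(0.0, intercept_sd)
        v = rng.normal(0.0, slope_sd)
        x = rng.normal(x_mean, x_sd, n_genes)
        y = (intercept + u) + (slope + v) * x + rng.normal(0.0, noise_sd, n_genes)
        frames.append(pd.DataFrame({
            "gene": [f"gene_{i + 1:05d}" for i in range(n_genes)],
            "replicate": f"R{r}", "log_molpct": x, "log_rpkm": y}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedStudy:
    """Bundle of all generated artefacts."""
    config: SimConfig
    truth: GroundTruth
    records: list
    annotations: pd.DataFrame
    psms: pd.DataFrame
    counts: pd.DataFrame
    gene_lengths: pd.Series

    @property
    def design(self) -> pd.DataFrame:
        return self.truth.design


def simulate_study(cfg: SimConfig, outdir=None) -> SimulatedStudy:
    """Run the whole generator; optionally write all artefacts to ``outdir``."""
    truth, records, annotations = generate_protein_db(cfg)
    psms = simulate_psm_table(cfg, truth)
    counts, lengths = simulate_counts(cfg, truth)
    study = SimulatedStudy(cfg, truth, records, annotations, psms,
                           counts, lengths)
    if outdir is not None:
        write_study(study, outdir)
    return study


_FLOAT_FMT = "%.15g"


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write FASTA + TSV artefacts (design, annotations, PSMs, counts,
    lengths, truth) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(study.records, str(outdir / "proteins.fasta"), "fasta")
    _write_tsv(study.annotations, outdir / "annotations.tsv")
    _write_tsv(study.design, outdir / "design.tsv")
    _write_tsv(study.psms, outdir / "psms.tsv")
    _write_tsv(study.counts.rename_axis("gene_id"), outdir / "counts.tsv",
               index=True)
    _write_tsv(study.gene_lengths.rename("length_bp").rename_axis("gene_id")
               .reset_index(), outdir / "gene_lengths.tsv")
    _write_tsv(study.truth.genes, outdir / "truth.tsv")
    if study.truth.planted_sets is not None:
        _write_tsv(study.truth.planted_sets, outdir / "truth_planted_sets.tsv")
    _write_tsv(study.truth.protein_log2.rename_axis("accession"),
               outdir / "truth_protein_log2.tsv", index=True)
    _write_tsv(study.truth.mrna_log2.rename_axis("gene_id"),
               outdir / "truth_mrna_log2.tsv", index=True)
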