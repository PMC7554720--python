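"""End-to-end orchestration: simulate -> quantify -> DE -> correlate ->
compartments -> enrich, driven by one config, with a machine-readable run
report.

Every stage output is a TSV with a versioned header comment, and a rerun
with the same seed reproduces all outputs byte-identically (no timestamps
go into files; wall times only appear in log lines).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import compartments as comp_mod
from . import correlation as corr_mod
from . import differential as de_mod
from . import enrichment as enr_mod
from . import simulate as sim_mod
from . import tmt_quant as quant_mod

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class Thresholds:
    """All printed significance thresholds, overridable per run.

    ``protein_p_thresholds`` maps a contrast label to the raw-p cutoff used
    for the run-report significance tier (the volcano raw-p segment); set a
    contrast's value to None to use the BH tier ``p_adj < protein_alpha``
    instead (coarse on small exact-permutation designs — see docs).
    """
    protein_alpha: float = 0.05
    protein_p_thresholds: dict = field(default_factory=lambda: {
        "N-/C": 0.05, "P-/C": 0.05})
    transcript_alpha: float = 0.05
    transcript_l2fc_min: float = 1.0
    rpkm_min: float = 2.0
    logistic_fdr: float = 0.01
    fisher_alpha: float = 0.05
    set_q: float = 0.05
    min_set_size: int = 5       # logistic & fisher: >=5; set-level test: >5
    protein_fdr: float = 0.03
    peptide_fdr: float = 0.03
    min_unique_peptides: int = 2

    def validate(self) -> None:
        for name in ("protein_alpha", "transcript_alpha", "logistic_fdr",
                     "fisher_alpha", "set_q", "protein_fdr", "peptide_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.rpkm_min < 0 or self.transcript_l2fc_min < 0:
            raise ValueError("rpkm_min and transcript_l2fc_min must be >= 0")


@dataclass
class RunConfig:
    """One document configuring the whole pipeline."""
    outdir: str = "pamuslink_run"
    seed: int = 0
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "quantify": True, "de": True,
        "correlate": True, "compartments": True, "enrich": True})
    multi_assign_compartments: bool = False

    def __post_init__(self):
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = doc.pop("sim", {})
        thr_doc = doc.pop("thresholds", {})
        for key in ("coupling_mix", "seq_length_range", "days"):
            if key in sim_doc and isinstance(sim_doc[key], list):
                sim_doc[key] = tuple(sim_doc[key])
        cfg = cls(sim=sim_mod.SimConfig(**sim_doc),
                  thresholds=Thresholds(**thr_doc), **doc)
        return cfg

    def validate(self) -> None:
        self.sim.validate()
        self.thresholds.validate()


@dataclass
class RunReport:
    """Per-stage feature counts plus config echo; written as JSON."""
    version: str
    seed: int
    counts: dict
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_table(df: pd.DataFrame, path: Path, table: str,
                index: bool = False) -> None:
    """TSV with a versioned header comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pamuslink v{__version__} schema={SCHEMA_VERSION} "
                 f"table={table}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.15g")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def summarize_top_table(de_table: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Top-k up- and downregulated features ranked by |L2fc|.

    Ties in |L2fc| break by ascending p then lexicographic feature id.
    Returns stacked blocks with a ``direction`` column and a 1-based rank.
    """
    if len(de_table) == 0:
        raise ValueError("empty DE table")
    de = de_table.copy()
    de = de[np.isfinite(de["l2fc"])]
    blocks = []
    for direction, sub in (("up", de[de["l2fc"] > 0]),
                           ("down", de[de["l2fc"] < 0])):
        sub = sub.assign(_abs=sub["l2fc"].abs())
        sub = sub.sort_values(["_abs", "p_raw", "feature"],
                              ascending=[False, True, True]).head(k)
        sub = sub.drop(columns="_abs")
        sub.insert(0, "rank", range(1, len(sub) + 1))
        sub.insert(1, "direction", direction)
        blocks.append(sub)
    return pd.concat(blocks, ignore_index=True)[
        ["rank", "direction", "feature", "l2fc", "p_raw", "p_adj",
         "significant", "contrast"]]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run all enabled stages, writing outputs under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    counts: dict = {}

    def _stage(name):
        enabled = cfg.stages.get(name, True)
        if not enabled:
            logger.info("stage %s: skipped (disabled)", name)
        return enabled

    t0 = time.perf_counter()
    if not _stage("simulate"):
        raise ValueError("the pipeline requires the simulate stage "
                         "(file-based entry points are the subcommands)")
    study = sim_mod.simulate_study(cfg.sim, outdir=outdir)
    design = study.design
    counts["n_genes_simulated"] = int(cfg.sim.n_genes)
    counts["n_psms_simulated"] = int(len(study.psms))
    logger.info("stage simulate: %.2fs, %d genes, %d PSMs",
                time.perf_counter() - t0, cfg.sim.n_genes, len(study.psms))

    if not _stage("quantify"):
        return _finish(cfg, counts, outdir)
    t0 = time.perf_counter()
    filtered = quant_mod.filter_identifications(
        study.psms, protein_fdr=thr.protein_fdr, peptide_fdr=thr.peptide_fdr,
        min_unique_peptides=thr.min_unique_peptides)
    chan = list(quant_mod.CHANNEL_COLUMNS)
    corrected = filtered.copy()
    corrected[chan] = quant_mod.correct_isotope_impurities(
        filtered[chan].to_numpy(float), cfg.sim.impurity())
    quant = quant_mod.pamus_quantify(corrected, study.truth.sequences, design)
    write_table(quant, outdir / "protein_quant.tsv", "protein_quant")
    molpct = quant_mod.molpct_matrix(quant)
    counts["n_proteins_quantified"] = int(len(quant))
    logger.info("stage quantify: %.2fs, %d proteins",
                time.perf_counter() - t0, len(quant))

    de_prot = {}
    de_trans_frames = []
    if _stage("de"):
        t0 = time.perf_counter()
        for contrast in (("N-", "C"), ("P-", "C")):
            import warnings as _w
            label = f"{contrast[0]}/{contrast[1]}"
            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                de = de_mod.protein_de(
                    molpct, design, contrast=contrast,
                    alpha=thr.protein_alpha,
                    p_threshold=thr.protein_p_thresholds.get(label),
                    seed=cfg.seed)
            de_prot[f"{contrast[0]}/{contrast[1]}"] = de
            key = contrast[0].rstrip("-")
            counts[f"n_sig_proteins_{key}"] = int(de["significant"].sum())
            counts[f"raw_p_cutoff_{key}"] = de_mod.corrected_raw_threshold(
                de["p_raw"], thr.protein_alpha)
        write_table(pd.concat(de_prot.values(), ignore_index=True),
                    outdir / "de_proteins.tsv", "de_proteins")
        for contrast in (("N-", "C"), ("P-", "C")):
            for day in cfg.sim.days:
                de = de_mod.transcript_de(
                    study.counts, design, contrast=contrast, day=day,
                    alpha=thr.transcript_alpha,
                    l2fc_min=thr.transcript_l2fc_min, seed=cfg.seed)
                de_trans_frames.append(de)
                key = f"{contrast[0].rstrip('-')}_day{day}"
                counts[f"n_deg_{key}"] = int(de["significant"].sum())
                counts[f"n_deg_up_{key}"] = int(
                    (de["significant"] & (de["l2fc"] > 0)).sum())
                counts[f"n_deg_down_{key}"] = int(
                    (de["significant"] & (de["l2fc"] < 0)).sum())
        de_trans = pd.concat(de_trans_frames, ignore_index=True)
        write_table(de_trans, outdir / "de_transcripts.tsv", "de_transcripts")
        top = summarize_top_table(de_prot["N-/C"], k=30)
        write_table(top, outdir / "top_proteins_N.tsv", "top_proteins")
        logger.info("stage de: %.2fs", time.perf_counter() - t0)

    if _stage("correlate") and de_prot:
        t0 = time.perf_counter()
        rpkm = corr_mod.compute_rpkm(study.counts, study.gene_lengths)
        write_table(rpkm.rename_axis("gene_id"), outdir / "rpkm.tsv",
                    "rpkm", index=True)
        acc_to_gene = dict(zip(study.annotations["accession"],
                               study.annotations["gene_id"]))
        fc_results = {}
        for label, de in de_prot.items():
            group = label.split("/")[0]
            tr = [f for f in de_trans_frames
                  if f["contrast"].iloc[0] == f"{label} day{cfg.sim.proteome_day}"]
            if not tr:
                continue
            prot_fc = pd.Series(de["l2fc"].to_numpy(),
                                index=de["feature"].map(acc_to_gene))
            tran_fc = pd.Series(tr[0]["l2fc"].to_numpy(),
                                index=tr[0]["feature"])
            fc_results[label] = corr_mod.l2fc_correlation(prot_fc, tran_fc)
        pairs = corr_mod.matched_abundance_pairs(
            molpct, rpkm, design, annotations=study.annotations,
            rpkm_min=thr.rpkm_min)
        mixed = corr_mod.fit_pooled_mixed_model(pairs)
        fits, summary, exclusions = corr_mod.per_gene_regressions(
            pairs, de_table=de_prot["N-/C"])
        census_all = corr_mod.slope_sign_census(fits, only_significant=False)
        census_sig = (corr_mod.slope_sign_census(fits, only_significant=True)
                      if fits["significant"].any() else None)
        report = corr_mod.correlation_report(fc_results, mixed, summary,
                                             census_all, census_sig)
        write_table(report, outdir / "correlation_report.tsv",
                    "correlation_report")
        write_table(fits, outdir / "per_gene_fits.tsv", "per_gene_fits")
        counts["n_pairs_pooled_model"] = int(mixed.n_pairs)
        counts["n_per_gene_models"] = int(summary["n_models"])
        counts["median_r2_all"] = summary["median_r2_all"]
        counts["median_r2_significant"] = summary["median_r2_significant"]
        counts["pooled_fixed_slope"] = mixed.slope
        counts["pooled_pearson_r2"] = mixed.pooled_r2
        logger.info("stage correlate: %.2fs", time.perf_counter() - t0)

    if _stage("compartments") and de_prot:
        t0 = time.perf_counter()
        assignments = comp_mod.assign_compartments(
            study.annotations, multi=cfg.multi_assign_compartments)
        summaries = [comp_mod.compartment_l2fc_distribution(de, assignments)
                     for de in de_prot.values()]
        comp_summary = pd.concat(summaries, ignore_index=True)
        write_table(comp_summary, outdir / "compartment_summary.tsv",
                    "compartment_summary")
        counts["n_compartments"] = int(comp_summary["compartment"].nunique())
        logger.info("stage compartments: %.2fs", time.perf_counter() - t0)

    if _stage("enrich") and de_prot:
        t0 = time.perf_counter()
        go_sets = enr_mod.sets_from_annotations(study.annotations, "go_terms")
        ko_sets = enr_mod.sets_from_annotations(study.annotations, "ko_terms")
        de_n = de_prot["N-/C"]
        l2fc = pd.Series(de_n["l2fc"].to_numpy(), index=de_n["feature"])
        labels = pd.Series(
            np.where(~de_n["significant"], "ns",
                     np.where(de_n["l2fc"] > 0, "up", "down")),
            index=de_n["feature"])
        frames = [enr_mod.logistic_gsea(l2fc, go_sets,
                                        fdr_cutoff=thr.logistic_fdr,
                                        min_members=thr.min_set_size)]
        for direction in ("up", "down"):
            frames.append(enr_mod.fisher_enrichment(
                labels, go_sets, direction, alpha=thr.fisher_alpha,
                min_members=thr.min_set_size))
        frames.append(enr_mod.set_level_test(
            l2fc, ko_sets, min_members=thr.min_set_size,
            q_cutoff=thr.set_q, mode="unidirectional"))
        enrich = pd.concat(frames, ignore_index=True)
        write_table(enrich, outdir / "enrichment.tsv", "enrichment")
        counts["n_terms_tested"] = int(enrich["term"].nunique())
        counts["n_terms_significant"] = int(
            enrich.loc[enrich["significant"], "term"].nunique())
        logger.info("stage enrich: %.2fs", time.perf_counter() - t0)

    return _finish(cfg, counts, outdir)


def _finish(cfg: RunConfig, counts: dict, outdir: Path) -> RunReport:
    report = RunReport(version=__version__, seed=cfg.seed, counts=counts,
                       config=dataclasses.asdict(cfg))
    (outdir / "run_report.json").write_text(report.to_json() + "\n")
    return report
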