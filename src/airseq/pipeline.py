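"""End-to-end orchestration: simulate -> DE -> classify -> CpG -> motifs
-> families -> QC -> report.

Each stage reads its inputs from the run directory and writes plain-text
outputs there, so stages can be re-run in isolation and a rerun with the
same config (including seed) reproduces every output byte-identically.
Output files carry no timestamps; the config hash and seed are recorded
once in ``run_meta.json`` and echoed in every JSON summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import cpg as cpg_mod
from . import de as de_mod
from . import families as fam_mod
from . import io as aio
from . import motifs as motif_mod
from . import qc as qc_mod
from .model import CONTRASTS, AnalysisParams, PromoterWindow
from .simulate import SimulationConfig, make_pwm_library, simulate_counts, simulate_promoters

STAGES = ("simulate", "de", "classify", "cpg", "motifs", "families", "qc", "report")


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimulationConfig | None = None
    counts_path: str | None = None
    sheet_path: str | None = None
    fasta_path: str | None = None
    annot_path: str | None = None
    pwm_path: str | None = None
    family_path: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    stages: tuple[str, ...] = STAGES
    nonresponsive_cell_types: tuple[str, ...] = ("eosinophil",)

    def __post_init__(self) -> None:
        if self.sim is None and self.counts_path is None:
            raise ValueError("need either a SimulationConfig or real input paths")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = self.sim.with_overrides(seed=self.seed)

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where it is written or
        # which subset of stages a particular invocation executed
        payload = _as_jsonable(self)
        payload.pop("outdir", None)
        payload.pop("stages", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        params = raw.pop("params", None)
        kwargs = dict(raw)
        if sim is not None:
            sim = {k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            kwargs["sim"] = SimulationConfig(**sim)
        if params is not None:
            params = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in params.items()}
            kwargs["params"] = AnalysisParams(**params)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "nonresponsive_cell_types" in kwargs:
            kwargs["nonresponsive_cell_types"] = tuple(
                kwargs["nonresponsive_cell_types"])
        return cls_(**kwargs)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    payload = {"meta": meta, **payload}
    path.write_text(json.dumps(_as_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _require(outdir: Path, filename: str, stage: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise DependencyError(f"stage '{stage}' needs missing input {filename}")
    return p


def write_gene_sets(sets: dict[str, set[str]], path: Path) -> None:
    """One set per line: set_name, n, comma-joined sorted genes."""
    with open(path, "w") as out:
        out.write("set_name\tn\tgenes\n")
        for name in sets:
            genes = ",".join(sorted(sets[name]))
            out.write(f"{name}\t{len(sets[name])}\t{genes}\n")


def read_gene_sets(path: Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row.set_name: set(row.genes.split(",")) if row.genes else set()
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path, meta: dict) -> None:
    sim = config.sim
    if sim is None:
        raise DependencyError("simulate stage requires a SimulationConfig")
    cm, truth = simulate_counts(sim)
    aio.write_counts(cm, outdir / "counts.tsv")
    aio.write_sample_sheet(cm, outdir / "samples.tsv")
    seqs, annots = simulate_promoters(
        truth, sim,
        window_length=config.params.window_length,
        tss_offset=config.params.promoter_upstream,
    )
    aio.write_fasta(seqs, outdir / "promoters.fasta")
    # single-base features: TSS = start on '+', end-1 on '-'
    with open(outdir / "promoters.bed", "w") as out:
        for a in annots:
            out.write(f"{a.sequence_id}\t{a.tss}\t{a.tss + 1}\t{a.gene}\t0\t{a.strand}\n")
    pwms, planted = make_pwm_library(sim)
    aio.write_pwms(pwms, outdir / "pwms.jaspar", scale=1000)
    aio.write_family_table(truth.family, outdir / "families.tsv")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    _write_json(outdir / "simulate.json", {
        "n_genes": sim.n_genes,
        "planted_pwms": sorted(planted),
        "responsive": sim.responsive,
    }, meta)


def _load_counts(config: RunConfig, outdir: Path, stage: str):
    if config.sim is not None:
        counts = _require(outdir, "counts.tsv", stage)
        sheet = _require(outdir, "samples.tsv", stage)
    else:
        counts, sheet = Path(config.counts_path), Path(config.sheet_path)
    return aio.read_counts(counts, sheet)


def stage_de(config: RunConfig, outdir: Path, meta: dict) -> None:
    cm = _load_counts(config, outdir, "de")
    sf = de_mod.size_factors(cm)
    de = de_mod.run_all_contrasts(cm, CONTRASTS, pseudocount=config.params.pseudocount)
    sf.rename("size_factor").to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
    de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    de_mod.condition_means(cm, sf).to_csv(
        outdir / "condition_means.tsv", sep="\t", index=False)
    _write_json(outdir / "de.json", {
        "n_tests": int(len(de)),
        "n_significant": int((de["qvalue"] < config.params.q_threshold).sum()),
    }, meta)


def stage_classify(config: RunConfig, outdir: Path, meta: dict) -> None:
    de = pd.read_csv(_require(outdir, "de_results.tsv", "classify"), sep="\t")
    cond_means = pd.read_csv(
        _require(outdir, "condition_means.tsv", "classify"), sep="\t")
    params = config.params
    regulation = cls.call_regulation(de, params)
    regulation.to_csv(outdir / "regulation.tsv", sep="\t", index=False)

    responsive = {ct: ct not in config.nonresponsive_cell_types
                  for ct in regulation["cell_type"].unique()}
    lps_up = cls.regulated_sets(regulation, "LPS_vs_ctrl", "up")
    lps_down = cls.regulated_sets(regulation, "LPS_vs_ctrl", "down")
    partition = cls.classify_air(lps_up, cond_means, params, responsive)
    il10_up = cls.il10_up_sets(regulation)
    specific_air = cls.celltype_specific_air(partition)

    sets_out: dict[str, set[str]] = {}
    for ct, genes in lps_up.items():
        sets_out[f"lps_up:{ct}"] = genes
    for ct, genes in lps_down.items():
        sets_out[f"lps_down:{ct}"] = genes
    for ct in partition.cell_types:
        sets_out[f"air:{ct}"] = partition.air[ct]
        sets_out[f"not_air:{ct}"] = partition.not_air[ct]
        sets_out[f"air_specific:{ct}"] = specific_air[ct]
    for ct, genes in il10_up.items():
        sets_out[f"il10_up:{ct}"] = genes
    write_gene_sets(sets_out, outdir / "gene_sets.tsv")

    summary: dict = {"set_sizes": {k: len(v) for k, v in sets_out.items()}}
    for label, collection in (
        ("lps_up", lps_up),
        ("air", partition.air),
        ("not_air", partition.not_air),
        ("il10_up", il10_up),
    ):
        if len(collection) >= 2:
            summary[f"partition_{label}"] = cls.venn_partition(collection).counts()
    _write_json(outdir / "classify.json", summary, meta)


def _load_windows(config: RunConfig, outdir: Path, stage: str):
    if config.sim is not None:
        fasta = _require(outdir, "promoters.fasta", stage)
        annot = _require(outdir, "promoters.bed", stage)
    else:
        fasta, annot = Path(config.fasta_path), Path(config.annot_path)
    paired, missing = aio.read_promoters(fasta, annot)
    windows: dict[str, PromoterWindow] = {}
    for gene, (seq, a) in paired.items():
        windows[gene] = cpg_mod.extract_window(a, {a.sequence_id: seq}, config.params)
    return windows, missing


def stage_cpg(config: RunConfig, outdir: Path, meta: dict) -> None:
    windows, missing = _load_windows(config, outdir, "cpg")
    sets = read_gene_sets(_require(outdir, "gene_sets.tsv", "cpg"))
    counts = pd.DataFrame({
        "gene": list(windows),
        "cg_count": [cpg_mod.cg_count(w) for w in windows.values()],
        "truncated": [w.truncated for w in windows.values()],
    })
    counts.to_csv(outdir / "cpg_counts.tsv", sep="\t", index=False)
    cell_types = sorted({k.split(":", 1)[1] for k in sets if k.startswith("air:")})
    background = list(windows.values())
    summaries = {}
    for ct in cell_types:
        air_w = [windows[g] for g in sets.get(f"air:{ct}", set()) if g in windows]
        na_w = [windows[g] for g in sets.get(f"not_air:{ct}", set()) if g in windows]
        if not air_w or not na_w:
            summaries[ct] = {"status": "skipped-empty-side"}
            continue
        summaries[ct] = cpg_mod.cpg_compare(
            air_w, na_w, background, config.params).to_dict()
    _write_json(outdir / "cpg_summary.json", {
        "per_cell_type": summaries,
        "missing_promoters": sorted(missing),
    }, meta)


def stage_motifs(config: RunConfig, outdir: Path, meta: dict) -> None:
    windows, _missing = _load_windows(config, outdir, "motifs")
    sets = read_gene_sets(_require(outdir, "gene_sets.tsv", "motifs"))
    pwm_path = (outdir / "pwms.jaspar" if config.sim is not None
                else Path(config.pwm_path))
    if not Path(pwm_path).exists():
        raise DependencyError("stage 'motifs' needs a PWM library")
    pwms = aio.read_pwms(pwm_path)
    air = {k.split(":", 1)[1]: v for k, v in sets.items() if k.startswith("air:")}
    not_air = {k.split(":", 1)[1]: v for k, v in sets.items()
               if k.startswith("not_air:")}
    partition = cls.AIRPartition(air=air, not_air=not_air)
    result = motif_mod.enrich_partition(pwms, partition, windows)
    result.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    _write_json(outdir / "motifs.json", {
        "n_pwms": len(pwms),
        "n_promoters": len(windows),
    }, meta)


def stage_families(config: RunConfig, outdir: Path, meta: dict) -> None:
    de = pd.read_csv(_require(outdir, "de_results.tsv", "families"), sep="\t")
    regulation = pd.read_csv(
        _require(outdir, "regulation.tsv", "families"), sep="\t")
    fam_path = (outdir / "families.tsv" if config.sim is not None
                else Path(config.family_path))
    families = aio.read_family_table(fam_path)
    params = config.params
    tests = []
    for contrast in ("LPS_vs_ctrl", "IL10_LPS_vs_LPS"):
        for ct in sorted(de["cell_type"].unique()):
            for fam in ("interleukin", "chemokine", "tnf"):
                tests.append(fam_mod.family_fc_test(
                    de, families, fam, contrast, ct, params).__dict__)
    pd.DataFrame(tests).to_csv(outdir / "family_tests.tsv", sep="\t", index=False)
    fam_mod.shared_cytokines(regulation, families, params=params).to_csv(
        outdir / "shared_cytokines.tsv", sep="\t", index=False)
    _write_json(outdir / "families.json", {"n_family_tests": len(tests)}, meta)


def stage_qc(config: RunConfig, outdir: Path, meta: dict) -> None:
    cm = _load_counts(config, outdir, "qc")
    sf = de_mod.size_factors(cm)
    rep = qc_mod.replicate_correlation(cm, sf)
    rep.to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)
    r2, order = qc_mod.r2_matrix(cm, sf)
    r2.to_csv(outdir / "r2_matrix.tsv", sep="\t")
    pca = qc_mod.pca_treatment_axis(cm, sf, config.params)
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca.treatment_association.to_csv(
        outdir / "pca_treatment_association.tsv", sep="\t", index=False)
    _write_json(outdir / "qc.json", {
        "replicate_r_min": float(rep["pearson_r"].min()) if len(rep) else None,
        "replicate_r_median": float(rep["pearson_r"].median()) if len(rep) else None,
        "n_flagged_pairs": int(rep["qc_flag"].sum()) if len(rep) else 0,
        "r2_leaf_order": order,
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
        "lps_axis": pca.lps_axis,
        "il10_axis": pca.il10_axis,
    }, meta)


def _truth_confusion(outdir: Path) -> dict | None:
    truth_path = outdir / "truth.tsv"
    sets_path = outdir / "gene_sets.tsv"
    if not (truth_path.exists() and sets_path.exists()):
        return None
    truth = pd.read_csv(truth_path, sep="\t")
    sets = read_gene_sets(sets_path)
    out: dict = {}
    for ct in truth["cell_type"].unique():
        sub = truth[truth["cell_type"] == ct]
        called_air = sets.get(f"air:{ct}")
        called_na = sets.get(f"not_air:{ct}")
        if called_air is None:
            continue
        classified = (called_air | called_na) if called_na else called_air
        sub = sub[sub["gene"].isin(classified)]
        t_air = set(sub.loc[sub["air"], "gene"])
        t_not = set(sub.loc[~sub["air"], "gene"])
        tp = len(t_air & called_air)
        fn = len(t_air - called_air)
        fp = len(t_not & called_air)
        tn = len(t_not - called_air)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        out[ct] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                   "sensitivity": sens, "specificity": spec,
                   "balanced_accuracy": (sens + spec) / 2.0}
    return out


def stage_report(config: RunConfig, outdir: Path, meta: dict) -> None:
    if not any(outdir.iterdir()):
        raise DependencyError("stage 'report' found an empty run directory")
    report: dict = {"partial": False}
    for name in ("classify", "qc"):
        p = outdir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
        else:
            report["partial"] = True
    cpg_p = outdir / "cpg_summary.json"
    if cpg_p.exists():
        report["cpg"] = json.loads(cpg_p.read_text())
    else:
        report["partial"] = True
    motif_p = outdir / "motif_enrichment.tsv"
    if motif_p.exists():
        enr = pd.read_csv(motif_p, sep="\t")
        enr = enr.dropna(subset=["z"])
        top = (enr.sort_values("z", ascending=False)
               .groupby(["cell_type", "side"]).head(3))
        report["top_motifs"] = [
            {k: (row[k] if not isinstance(row[k], np.generic) else row[k].item())
             for k in ("cell_type", "side", "pwm_id", "z", "qvalue")}
            for _, row in top.iterrows()
        ]
    else:
        report["partial"] = True
    confusion = _truth_confusion(outdir)
    if confusion is not None:
        report["air_confusion_vs_truth"] = confusion
    _write_json(outdir / "report.json", report, meta)

    lines = ["# airseq run report", ""]
    if report["partial"]:
        lines.append("**Partial run: some stages are missing.**")
    if "classify" in report:
        lines.append("## Gene-set sizes")
        for k, v in sorted(report["classify"].get("set_sizes", {}).items()):
            lines.append(f"- {k}: {v}")
    if "qc" in report:
        lines.append("")
        lines.append(f"LPS-associated PC: {report['qc'].get('lps_axis')}; "
                     f"IL-10-associated PC: {report['qc'].get('il10_axis')}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "classify": stage_classify,
    "cpg": stage_cpg,
    "motifs": stage_motifs,
    "families": stage_families,
    "qc": stage_qc,
    "report": stage_report,
}


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "params": _as_jsonable(config.params)}
    (outdir / "run_meta.json").write_text(
        json.dumps(_as_jsonable({
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "params": config.params,
            "sim": config.sim,
            "stages": list(config.stages),
        }), indent=2, sort_keys=True, default=str) + "\n")
    for stage in STAGES:
        if stage in config.stages:
            _STAGE_FUNCS[stage](config, outdir, meta)
    return outdir
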