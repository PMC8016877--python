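"""End-to-end orchestration: simulate -> preprocess -> quantify -> de ->
overlap -> targets -> phenostats, driven by one flat YAML/JSON config.

Each stage reads the previous stage's outputs from the run directory and
appends a record (paths + record counts) to the run manifest, which also
snapshots the effective configuration — including every defaulted mode flag
(literal/normalized counting, welch/permutation test, raw/corrected p) — so
a run documents the choices it was made with.  Reruns with the same config
and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import align_assign, de_overlap, phenostats, simgen, targets_enrich
from .errors import ConfigError
from .preprocess import DEFAULT_ADAPTER, preprocess_fastq, read_fastq, write_fastq
from .targets_enrich import revcomp

__version__ = "0.1.0"

log = logging.getLogger("trf_heritance")

KNOWN_STAGES = ["simulate", "preprocess", "quantify", "de", "overlap", "targets", "phenostats"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {"generations": ["F0", "F1"], "conditions": ["CO", "OID"]},
    "preprocess": {"min_overlap": 3, "max_mismatch_rate": 0.1, "window": 4,
                   "min_q": 15.0, "min_len": 15, "min_nt": 30, "max_nt": 45},
    "quantify": {"mode": "literal", "min_score": 85.0, "margin": 0.0,
                 "collapse": "by_isoacceptor", "write_assignments": True},
    "de": {"alpha": 0.05, "method": "welch_log", "use_raw_p": False,
           "length_normalize": False},
    "overlap": {},
    "targets": {"score_min": 150.0, "energy_max": -20.0, "fdr_max": 0.25,
                "n_genes": 60, "n_terms": 8, "genes_per_term_range": [10, 20],
                "utr_length": 300, "trf_length": 35, "n_planted_per_trf": 3},
    # defaults carry the study's group contrast: the treated lineage is more
    # insulin resistant (higher, flatter glucose curve) and develops tumors
    # earlier than controls
    "phenostats": {"groups": ["COxCO", "OIDxOID"], "n_per_group": 25,
                   "follow_up_weeks": 20.0,
                   "itt_curve_params": {
                       "COxCO": {"baseline": 120.0, "nadir_frac": 0.45, "noise_sd": 8.0},
                       "OIDxOID": {"baseline": 135.0, "nadir_frac": 0.60, "noise_sd": 8.0}},
                   "survival_params": {"COxCO": {"median_weeks": 18.0},
                                       "OIDxOID": {"median_weeks": 10.0}}},
}


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[str], counts: Mapping[str, Any]) -> None:
        self.stages.append({"name": name, "outputs": outputs, "counts": dict(counts)})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"version": self.version, "seed": self.seed,
             "config": self.config, "stages": self.stages},
            indent=2, sort_keys=True) + "\n")


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text()) or {}
    cfg = dict(config)
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("stages: a non-empty stage list is required")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"stages: unknown stage(s) {unknown}")
    # stages run in canonical order regardless of listing order
    cfg["stages"] = [s for s in KNOWN_STAGES if s in stages]
    for s in cfg["stages"]:
        section = cfg.get(s, {})
        if not isinstance(section, Mapping):
            raise ConfigError(f"{s}: section must be a mapping")
        cfg[s] = {**DEFAULTS.get(s, {}), **section}
    # adapter: preprocess may inherit the simulator's adapter
    if "preprocess" in cfg["stages"] and "adapter" not in cfg["preprocess"]:
        if "simulate" in cfg["stages"]:
            cfg["preprocess"]["adapter"] = cfg["simulate"].get("adapter", DEFAULT_ADAPTER)
        else:
            raise ConfigError("preprocess.adapter")
    return cfg


def _sample_name(gen: str, cond: str, rep: int) -> str:
    return f"{gen}_{cond}_{rep}"


def run_pipeline(config: str | Path | Mapping, outdir: str | Path | None = None,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages in order under ``outdir``.

    ``seed`` overrides the config's master seed.  Returns the manifest,
    which is also written to ``<outdir>/manifest.json``.
    """
    cfg = load_config(config)
    out = Path(outdir if outdir is not None else cfg.get("outdir", "trf_run"))
    out.mkdir(parents=True, exist_ok=True)
    master = int(seed if seed is not None else cfg.get("seed", 0))
    cfg["seed"] = master
    manifest = RunManifest(__version__, master, cfg)

    state: dict[str, Any] = {}
    for stage in cfg["stages"]:
        t0 = time.perf_counter()
        runner = globals()[f"_stage_{stage}"]
        try:
            runner(cfg, out, master, manifest, state)
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest


def analyze_study(
    seed: int,
    ref: simgen.TRNAReference | None = None,
    sim_config: simgen.SimConfig | None = None,
    mode: str = "normalized",
    alpha: float = 0.05,
    method: str = "welch_log",
    generations: tuple[str, ...] = ("F0", "F1"),
    conditions: tuple[str, ...] = ("CO", "OID"),
) -> dict[str, Any]:
    """In-memory run of simulate -> preprocess -> quantify -> DE -> overlap
    on the packaged study fixture (no files written).

    Returns per-generation isoacceptor count matrices, sample->condition
    maps, DE tables, the cross-generation overlap report and per-sample
    count-table objects (for conservation checks).
    """
    from .preprocess import preprocess_reads

    ref = ref if ref is not None else simgen.study_reference()
    sconf = sim_config if sim_config is not None else simgen.SimConfig()
    index = align_assign.ReferenceIndex(ref)
    libs = simgen.simulate_experiment(ref, sconf, seed, generations=generations,
                                      conditions=conditions)
    tables: dict[str, list] = {g: [] for g in generations}
    names: dict[str, list] = {g: [] for g in generations}
    groups: dict[str, dict] = {g: {} for g in generations}
    for (gen, cond, rep), (records, _) in libs.items():
        clean, _ = preprocess_reads(records, adapter=sconf.adapter)
        name = _sample_name(gen, cond, rep)
        tables[gen].append(align_assign.quantify_sample(clean, index, mode=mode,
                                                        sample=name))
        names[gen].append(name)
        groups[gen][name] = cond
    counts = {g: align_assign.count_matrix(tables[g], ref,
                                           collapse="by_isoacceptor",
                                           sample_names=names[g])
              for g in generations}
    de = {}
    for g in generations:
        expr = de_overlap.tpm_normalize(counts[g], groups=groups[g])
        de[g] = de_overlap.de_test(expr, conditions[0], conditions[1],
                                   alpha=alpha, method=method)
    overlap = de_overlap.overlap_analysis(de[generations[0]], de[generations[1]])
    return {"reference": ref, "counts": counts, "groups": groups, "de": de,
            "overlap": overlap, "tables": tables}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _build_reference(cfg: dict, out: Path, state: dict) -> simgen.TRNAReference:
    if "reference" not in state:
        sim = cfg.get("simulate", {})
        if "reference_fasta" in sim:
            ref = simgen.TRNAReference.read_fasta(sim["reference_fasta"])
        else:
            ref = simgen.study_reference()
        ref.write_fasta(out / "reference.fasta")
        state["reference"] = ref
    return state["reference"]


def _stage_simulate(cfg, out: Path, seed, manifest, state) -> None:
    sec = cfg["simulate"]
    ref = _build_reference(cfg, out, state)
    sim_fields = {k: v for k, v in sec.items()
                  if k in simgen.SimConfig.__dataclass_fields__}
    if "length_window" in sim_fields:
        sim_fields["length_window"] = tuple(sim_fields["length_window"])
    sconf = simgen.SimConfig(**sim_fields)
    raw = out / "raw"
    raw.mkdir(exist_ok=True)
    libs = simgen.simulate_experiment(ref, sconf, seed,
                                      generations=sec["generations"],
                                      conditions=sec["conditions"])
    counts, outputs, truths = {}, [], []
    for (gen, cond, rep), (records, truth) in libs.items():
        name = _sample_name(gen, cond, rep)
        path = raw / f"{name}.fastq"
        write_fastq(records, path)
        truth.reads.to_csv(raw / f"{name}.truth.tsv", sep="\t", index=False)
        outputs.append(str(path))
        truths.append(truth)
        counts[name] = len(records)
    state["raw"] = {k: str(raw / f"{_sample_name(*k)}.fastq") for k in libs}
    state["design"] = list(libs)
    state["truths"] = dict(zip(libs, truths))
    manifest.add("simulate", outputs, counts)


def _stage_preprocess(cfg, out: Path, seed, manifest, state) -> None:
    sec = cfg["preprocess"]
    if "raw" in state:
        inputs = state["raw"]
    else:
        paths = sec.get("inputs")
        if not paths:
            raise ConfigError("preprocess.inputs")
        inputs = {Path(p).stem: p for p in paths}
        for p in inputs.values():
            if not Path(p).exists():
                raise FileNotFoundError(f"input FASTQ not found: {p}")
    clean = out / "clean"
    clean.mkdir(exist_ok=True)
    rows, counts, outputs = [], {}, []
    cleaned = {}
    for key, path in inputs.items():
        name = _sample_name(*key) if isinstance(key, tuple) else key
        dst = clean / f"{name}.fastq"
        stats = preprocess_fastq(
            path, dst, adapter=sec["adapter"], min_overlap=sec["min_overlap"],
            max_mismatch_rate=sec["max_mismatch_rate"], window=sec["window"],
            min_mean_q=sec["min_q"], min_len=sec["min_len"],
            min_nt=sec["min_nt"], max_nt=sec["max_nt"],
        )
        rows.append({"sample": name, **stats.as_row()})
        counts[name] = {"in": stats.n_input, "out": stats.n_size_selected}
        cleaned[key] = str(dst)
        outputs.append(str(dst))
    pd.DataFrame(rows).to_csv(out / "preprocess_stats.tsv", sep="\t", index=False)
    state["clean"] = cleaned
    manifest.add("preprocess", outputs, counts)


def _stage_quantify(cfg, out: Path, seed, manifest, state) -> None:
    sec = cfg["quantify"]
    ref = _build_reference(cfg, out, state)
    if "clean" not in state:
        raise ConfigError("quantify requires a preprocess stage (or quantify.inputs)")
    index = align_assign.ReferenceIndex(ref)
    tables, names, counts = [], [], {}
    for key, path in state["clean"].items():
        name = _sample_name(*key) if isinstance(key, tuple) else key
        reads = list(read_fastq(path))
        assignments = align_assign.assign_reads(
            reads, index, min_score_percent=sec["min_score"],
            best_margin_percent=sec["margin"])
        if sec["write_assignments"]:
            adir = out / "assignments"
            adir.mkdir(exist_ok=True)
            align_assign.assignments_frame(assignments).to_csv(
                adir / f"{name}.tsv", sep="\t", index=False)
        table = align_assign.weighted_counts(assignments, mode=sec["mode"], sample=name)
        tables.append(table)
        names.append(name)
        counts[name] = table.totals
    mat = align_assign.count_matrix(tables, ref, collapse=sec["collapse"],
                                    sample_names=names)
    mat.to_csv(out / "counts.tsv", sep="\t")
    state["counts"] = mat
    manifest.add("quantify", [str(out / "counts.tsv")], counts)


def _de_for_generation(cfg, state, gen: str) -> pd.DataFrame:
    sec = cfg["de"]
    mat = state["counts"]
    cols = [c for c in mat.columns if c.startswith(f"{gen}_")]
    groups = {c: c.split("_")[1] for c in cols}
    ref = state.get("reference")
    lengths = {e.isoacceptor: e.length for e in ref.entries} if ref else None
    expr = de_overlap.tpm_normalize(mat[cols], groups=groups, lengths=lengths,
                                    length_normalize=sec["length_normalize"])
    conds = cfg.get("simulate", {}).get("conditions", ["CO", "OID"])
    return de_overlap.de_test(expr, conds[0], conds[1], alpha=sec["alpha"],
                              method=sec["method"], use_raw_p=sec["use_raw_p"])


def _stage_de(cfg, out: Path, seed, manifest, state) -> None:
    if "counts" not in state:
        raise ConfigError("de requires a quantify stage")
    gens = cfg.get("simulate", {}).get("generations", ["F0", "F1"])
    results, outputs, counts = {}, [], {}
    for gen in gens:
        res = _de_for_generation(cfg, state, gen)
        path = out / f"de_{gen}.tsv"
        res.to_csv(path, sep="\t")
        results[gen] = res
        outputs.append(str(path))
        counts[gen] = {"n_species": len(res), "n_significant": int(res["significant"].sum())}
    state["de"] = results
    manifest.add("de", outputs, counts)


def _stage_overlap(cfg, out: Path, seed, manifest, state) -> None:
    if "de" not in state or len(state["de"]) < 2:
        raise ConfigError("overlap requires a de stage over two generations")
    gens = list(state["de"])
    report = de_overlap.overlap_analysis(state["de"][gens[0]], state["de"][gens[1]])
    df = pd.DataFrame(
        {"species": report.species,
         "direction": [report.directions[s] for s in report.species]})
    df.to_csv(out / "overlap.tsv", sep="\t", index=False)
    state["overlap"] = report
    manifest.add("overlap", [str(out / "overlap.tsv")],
                 {"n_shared": len(report.species), "n_up": report.n_up_shared,
                  "n_down": report.n_down_shared})


def _stage_targets(cfg, out: Path, seed, manifest, state) -> None:
    sec = cfg["targets"]
    ref = _build_reference(cfg, out, state)
    if "overlap" in state:
        species = state["overlap"].species
    else:
        species = sec.get("trf_species", ref.isoacceptors[:5])
    trfs = {}
    for iso in species:
        member = ref.members(iso)[0]
        trfs[f"tRF-{iso}"] = member.sequence[: sec["trf_length"]]

    # synthetic annotation space with planted target sites for the query tRFs
    genes = [f"G{i + 1:04d}" for i in range(sec["n_genes"])]
    planted_sites: dict[str, str] = {}
    planted_terms: dict[str, set] = {}
    # all planted targets share one term so the demo enrichment has signal
    gi = 0
    for trf_id, seq in trfs.items():
        for _ in range(sec["n_planted_per_trf"]):
            gene = genes[gi % len(genes)]
            planted_sites[gene] = revcomp(seq)
            planted_terms.setdefault("T001", set()).add(gene)
            gi += 1
    utrs, annot = simgen.make_annotation_db(
        sec["n_genes"], sec["n_terms"], tuple(sec["genes_per_term_range"]),
        sec["utr_length"], planted=planted_terms, planted_sites=planted_sites,
        seed=int(seed) + 17)
    with open(out / "utrs.fasta", "w") as fh:
        for g, s in utrs:
            fh.write(f">{g}\n{s}\n")
    annot.to_csv(out / "annotation.tsv", sep="\t", index=False)

    hits = targets_enrich.predict_targets(
        trfs, dict(utrs), score_min=sec["score_min"], energy_max=sec["energy_max"])
    hits_df = pd.DataFrame([h.__dict__ for h in hits])
    hits_df.to_csv(out / "targets.tsv", sep="\t", index=False)
    query = sorted({h.gene_id for h in hits})
    enr = targets_enrich.enrich(query, annot, genes, fdr_max=sec["fdr_max"])
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    state["targets"] = hits
    state["enrichment"] = enr
    manifest.add("targets",
                 [str(out / "targets.tsv"), str(out / "enrichment.tsv")],
                 {"n_trfs": len(trfs), "n_target_genes": len(query),
                  "n_enriched_terms": len(enr)})


def _stage_phenostats(cfg, out: Path, seed, manifest, state) -> None:
    sec = cfg["phenostats"]
    glucose, survival = simgen.simulate_phenotypes(
        sec["groups"], sec["n_per_group"],
        itt_curve_params=sec.get("itt_curve_params"),
        survival_params=sec.get("survival_params"),
        seed=seed, follow_up_weeks=sec["follow_up_weeks"])
    glucose.to_csv(out / "glucose.tsv", sep="\t", index=False)
    survival.to_csv(out / "survival.tsv", sep="\t", index=False)

    aucs = glucose.groupby(["group", "animal_id"], sort=True).apply(
        lambda d: phenostats.trapezoid_auc(d["time_min"], d["glucose_mg_dl"]),
        include_groups=False)
    auc_df = aucs.rename("auc").reset_index()
    auc_df.to_csv(out / "itt_auc.tsv", sep="\t", index=False)
    groups = [auc_df.loc[auc_df["group"] == g, "auc"].to_numpy() for g in sec["groups"]]
    f_auc, p_auc = phenostats.oneway_anova(groups)
    tw = phenostats.twoway_anova(glucose.rename(
        columns={"glucose_mg_dl": "value", "time_min": "time"}))
    chi2, p_lr = phenostats.logrank(survival.rename(columns={"time_weeks": "time"}),
                                    sec["groups"][0], sec["groups"][-1])
    results = pd.DataFrame(
        [("auc_oneway_anova", f_auc, p_auc),
         ("itt_twoway_group", tw.loc["group", "F"], tw.loc["group", "p_value"]),
         ("itt_twoway_time", tw.loc["time", "F"], tw.loc["time", "p_value"]),
         ("itt_twoway_interaction", tw.loc["group:time", "F"],
          tw.loc["group:time", "p_value"]),
         ("incidence_logrank", chi2, p_lr)],
        columns=["analysis", "statistic", "p_value"])
    results.to_csv(out / "phenostats.tsv", sep="\t", index=False)
    state["phenostats"] = results
    manifest.add("phenostats",
                 [str(out / "glucose.tsv"), str(out / "survival.tsv"),
                  str(out / "phenostats.tsv")],
                 {"n_animals": int(survival.shape[0]),
                  "n_events": int(survival["event"].sum())})
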