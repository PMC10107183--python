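"""Configuration-driven orchestration of the full analysis chain.

``run`` executes the stages simulate -> de -> enrich -> ewce -> signature ->
qc -> opls -> mwas -> report in dependency order, writing every stage's
tables under the output directory and a machine-readable manifest with
parameters and content hashes.  A stage whose parameter/input hash is
unchanged from the recorded manifest is skipped (no-op rerun).  ``report``
renders a Markdown summary from the JSON it also emits.

The numbered scripts under ``analysis/`` are thin drivers over the same
stage functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrich, ewce, mwas, opls, qc, signature, synthetic, univariate
from .network import extract_subnetwork, map_elements, write_network

__all__ = ["RunConfig", "run", "report", "STAGES"]

STAGES = ["simulate", "de", "enrich", "ewce", "signature", "qc", "opls",
          "mwas", "report"]


@dataclasses.dataclass
class RunConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: list = dataclasses.field(default_factory=lambda: list(STAGES))
    sim: dict = dataclasses.field(default_factory=dict)   # SimConfig overrides
    alpha: float = 0.05
    sam_target_fdr: float = 0.03
    sam_target_fdr_q90: float = 0.05
    itraq_upper: float = 1.17
    itraq_lower: float = 0.83
    presence: float = 0.5
    cv_max: float = 20.0
    knn_k: int = 5
    vip_threshold: float = 1.0
    rfc_min: float = 0.5
    n_perm_opls: int = 20
    n_boot_ewce: int = 2000
    n_perm_mwsl: int = 1000
    fwer: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def _read_tsv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _stage_key(name: str, params: dict, inputs: list[Path]) -> str:
    payload = json.dumps({"stage": name, "params": params,
                          "inputs": {str(p): _sha(p) for p in sorted(inputs)}},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig | str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}

    simcfg = synthetic.SimConfig(seed=config.seed, **config.sim)

    def record(name: str, outputs: list[Path], params: dict, key: str,
               skipped: bool = False, **extra) -> None:
        manifest["stages"][name] = {
            "key": key, "skipped": skipped, "params": params,
            "outputs": {p.name: _sha(p) for p in outputs}, **extra,
        }

    def need(stage: str, upstream: str, paths: list[Path]) -> None:
        missing = [p.name for p in paths if not p.exists()]
        if missing:
            raise RuntimeError(
                f"stage {stage!r} requires outputs of stage {upstream!r} "
                f"(missing: {missing}); run that stage first")

    def fresh(name: str, params: dict, inputs: list[Path],
              outputs: list[Path]) -> tuple[bool, str]:
        key = _stage_key(name, params, [p for p in inputs if p.exists()])
        prev = previous.get("stages", {}).get(name)
        if prev and prev.get("key") == key and all(p.exists() for p in outputs):
            return False, key
        return True, key

    # ---- simulate --------------------------------------------------------
    p = {"sim": dataclasses.asdict(simcfg)}
    sim_outputs = [out / n for n in (
        "network.json", "xref.tsv", "expansion.tsv", "expression.tsv",
        "expression_labels.tsv", "proteomics.tsv", "proteomics_flags.tsv",
        "lipidomics.tsv", "lipidomics_meta.tsv", "lipid_annotation.tsv",
        "celltype_expr.tsv", "truth.json")]
    if "simulate" in config.stages:
        do, key = fresh("simulate", p, [], sim_outputs)
        if do:
            net, xref, expansion = synthetic.gen_gsmn(simcfg)
            # plant transcriptomic DE inside the lipid pathways' gene sets so
            # enrichment and subnetwork extraction have signal to find
            lipid_pwys = [f"PWY{i:03d}" for i in range(simcfg.n_lipid_pathways)]
            lipid_genes = sorted(extract_subnetwork(net, lipid_pwys).genes)
            net_genes = sorted(net.genes)
            filler = [f"G{i:05d}" for i in range(simcfg.n_genes - len(net_genes))]
            gene_ids = net_genes + filler
            de_targets = lipid_genes[:simcfg.n_de_genes]
            expr, labels, t_expr = synthetic.gen_expression(
                simcfg, gene_ids=gene_ids, de_gene_ids=de_targets)
            prot, flags, plabels, t_prot = synthetic.gen_proteomics(simcfg)
            lip, meta, annot, t_lip = synthetic.gen_lipidomics(
                simcfg, expansion=expansion,
                species_xref=xref[xref["lipid_id"] != ""])
            ct_expr, ct_set, ct_target, _ = synthetic.gen_celltype_reference(simcfg)

            write_network(net, out / "network.json")
            _write_tsv(xref, out / "xref.tsv", index=False)
            _write_tsv(expansion, out / "expansion.tsv", index=False)
            _write_tsv(expr, out / "expression.tsv")
            _write_tsv(pd.DataFrame({"sample": expr.columns, "group": labels}),
                       out / "expression_labels.tsv", index=False)
            _write_tsv(prot, out / "proteomics.tsv")
            _write_tsv(flags, out / "proteomics_flags.tsv")
            _write_tsv(lip, out / "lipidomics.tsv")
            _write_tsv(meta, out / "lipidomics_meta.tsv")
            _write_tsv(annot, out / "lipid_annotation.tsv", index=False)
            _write_tsv(ct_expr, out / "celltype_expr.tsv")
            truth = {
                "de_transcripts": sorted(t_expr.de_elements),
                "de_proteins": sorted(t_prot.de_elements),
                "signature_species": sorted(t_lip.signature_species),
                "enriched_pathways": lipid_pwys,
                "celltype_gene_set": sorted(ct_set),
                "celltype_target": ct_target,
                "seed": simcfg.seed,
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=1))
        record("simulate", sim_outputs, p, key, skipped=not do)

    # ---- differential expression ----------------------------------------
    de_outputs = [out / "de_transcripts.tsv", out / "de_proteins.tsv"]
    if "de" in config.stages:
        params = {"sam_target_fdr": config.sam_target_fdr,
                  "sam_target_fdr_q90": config.sam_target_fdr_q90,
                  "itraq": [config.itraq_lower, config.itraq_upper],
                  "alpha": config.alpha, "seed": config.seed}
        do, key = fresh("de", params, sim_outputs, de_outputs)
        if do:
            need("de", "simulate", sim_outputs)
            expr = _read_tsv(out / "expression.tsv")
            labels = pd.read_csv(out / "expression_labels.tsv", sep="\t")["group"]
            sam = de.sam_test(expr, labels, de.SamParams(
                target_fdr=config.sam_target_fdr,
                target_fdr_q90=config.sam_target_fdr_q90), seed=config.seed)
            _write_tsv(sam, out / "de_transcripts.tsv", index=False)

            prot = _read_tsv(out / "proteomics.tsv")
            flags = _read_tsv(out / "proteomics_flags.tsv").astype(bool)
            plabels = ["control"] * (prot.shape[1] // 2) + \
                ["treatment"] * (prot.shape[1] - prot.shape[1] // 2)
            clean = de.proteomics_clean(prot, flags, plabels)
            imputed = de.impute_downshifted_normal(clean, seed=config.seed)
            res = de.perm_ttest(imputed, plabels, alpha=config.alpha,
                                seed=config.seed)
            res = de.itraq_fc_filter(res, upper=config.itraq_upper,
                                     lower=config.itraq_lower)
            _write_tsv(res, out / "de_proteins.tsv", index=False)
        record("de", de_outputs, params, key, skipped=not do)

    # ---- pathway enrichment ----------------------------------------------
    enrich_out = [out / "enrichment.tsv", out / "mapped.json"]
    if "enrich" in config.stages:
        params = {"alpha": config.alpha}
        do, key = fresh("enrich", params, de_outputs, enrich_out)
        if do:
            need("enrich", "simulate", [out / "network.json"])
            need("enrich", "de", [out / "de_transcripts.tsv"])
            from .network import read_network
            net = read_network(out / "network.json")
            sam = pd.read_csv(out / "de_transcripts.tsv", sep="\t")
            called = sam.loc[sam["called"], "id"].astype(str).tolist()
            mapped = map_elements(called or sam["id"].astype(str).tolist(),
                                  net, "transcriptome")
            collection = enrich.pathway_gene_sets(net)
            if mapped.mapped:
                table = enrich.hypergeom_enrich(mapped.mapped, collection,
                                                alpha=config.alpha)
            else:  # nothing mapped: no enrichment to test
                table = pd.DataFrame(columns=["term", "k", "K", "n", "N", "p",
                                              "coverage", "q", "significant"])
            _write_tsv(table, out / "enrichment.tsv", index=False)
            (out / "mapped.json").write_text(json.dumps({
                "layer": mapped.layer, "n_input": len(mapped.input_ids),
                "n_mapped": len(mapped.mapped),
                "n_unmapped": len(mapped.unmapped)}, indent=1))
        record("enrich", enrich_out, params, key, skipped=not do)

    # ---- cell-type enrichment --------------------------------------------
    ewce_out = [out / "ewce.tsv"]
    if "ewce" in config.stages:
        params = {"n_boot": config.n_boot_ewce, "seed": config.seed}
        do, key = fresh("ewce", params, sim_outputs, ewce_out)
        if do:
            need("ewce", "simulate", [out / "celltype_expr.tsv", out / "truth.json"])
            ct_expr = _read_tsv(out / "celltype_expr.tsv")
            truth = json.loads((out / "truth.json").read_text())
            spec = ewce.specificity(ct_expr)
            res = ewce.ewce_test(truth["celltype_gene_set"], spec,
                                 n_boot=config.n_boot_ewce, seed=config.seed)
            _write_tsv(res, out / "ewce.tsv", index=False)
        record("ewce", ewce_out, params, key, skipped=not do)

    # ---- lipid signature --------------------------------------------------
    sig_out = [out / "signature.tsv", out / "signature_counts.json",
               out / "validated_features.json"]
    if "signature" in config.stages:
        params = {"alpha": config.alpha}
        do, key = fresh("signature", params, enrich_out, sig_out)
        if do:
            need("signature", "enrich", [out / "enrichment.tsv"])
            need("signature", "simulate", [out / "xref.tsv", out / "lipid_annotation.tsv"])
            from .network import read_network
            net = read_network(out / "network.json")
            table = pd.read_csv(out / "enrichment.tsv", sep="\t")
            truth = json.loads((out / "truth.json").read_text())
            lipid_labels = truth["enriched_pathways"]
            selected = signature.select_lipid_pathways(table, lipid_labels)
            sub = extract_subnetwork(net, sorted(selected))
            xref = pd.read_csv(out / "xref.tsv", sep="\t",
                               keep_default_na=False)
            annot = pd.read_csv(out / "lipid_annotation.tsv", sep="\t")
            sig = signature.build_signature(sub, xref, annot)
            val = signature.validate_signature(sig, annot)
            _write_tsv(sig.entries, out / "signature.tsv", index=False)
            (out / "signature_counts.json").write_text(json.dumps({
                "subnetwork": sub.counts, "predicted": sig.counts,
                "validated": val.counts, "selected_pathways": sorted(selected)},
                indent=1))
            (out / "validated_features.json").write_text(
                json.dumps(val.feature_ids, indent=1))
        record("signature", sig_out, params, key, skipped=not do)

    # ---- lipidomics QC -----------------------------------------------------
    qc_out = [out / "lipidomics_qc.tsv", out / "qc_report.tsv"]
    if "qc" in config.stages:
        params = {"presence": config.presence, "cv_max": config.cv_max,
                  "k": config.knn_k}
        do, key = fresh("qc", params, sim_outputs, qc_out)
        if do:
            need("qc", "simulate", [out / "lipidomics.tsv", out / "lipidomics_meta.tsv"])
            lip = _read_tsv(out / "lipidomics.tsv")
            meta = _read_tsv(out / "lipidomics_meta.tsv")
            normalized, rep, _ = qc.preprocess(
                lip, meta["is_qc_pool"].to_numpy(), presence=config.presence,
                cv_max=config.cv_max, k=config.knn_k)
            _write_tsv(normalized, out / "lipidomics_qc.tsv")
            _write_tsv(rep, out / "qc_report.tsv", index=False)
        record("qc", qc_out, params, key, skipped=not do)

    # ---- OPLS-DA + univariate ---------------------------------------------
    opls_out = [out / "opls_models.json", out / "vip.tsv",
                out / "univariate.tsv"]
    if "opls" in config.stages:
        params = {"n_perm": config.n_perm_opls, "seed": config.seed,
                  "vip_threshold": config.vip_threshold,
                  "rfc_min": config.rfc_min}
        do, key = fresh("opls", params, qc_out + sig_out, opls_out)
        if do:
            need("opls", "qc", [out / "lipidomics_qc.tsv"])
            need("opls", "signature", [out / "validated_features.json"])
            mat = _read_tsv(out / "lipidomics_qc.tsv")
            meta = _read_tsv(out / "lipidomics_meta.tsv")
            annot = pd.read_csv(out / "lipid_annotation.tsv", sep="\t")
            validated = json.loads((out / "validated_features.json").read_text())
            bio = meta.index[~meta["is_qc_pool"]]
            raw = mat.loc[bio]
            geno = meta.loc[bio, "genotype"]
            sex = meta.loc[bio, "sex"]

            models = {}
            vip_rows = []
            for name, cols in [("full", list(raw.columns)),
                               ("validated_signature",
                                sorted(set(sum(validated.values(), []))
                                       & set(raw.columns)))]:
                if len(cols) < 2:
                    continue
                scaled, _ = opls.log_pareto(raw[cols])
                m2 = opls.fit_oplsda(scaled, geno, n_ortho="auto",
                                     seed=config.seed)
                perm = opls.permutation_validate(
                    scaled, geno, n_ortho=m2.n_ortho,
                    n_perm=config.n_perm_opls, seed=config.seed)
                four = geno.astype(str) + ":" + sex.astype(str)
                m4 = opls.fit_oplsda(scaled, four, n_ortho=0, seed=config.seed)
                models[name] = {
                    "two_class": m2.summary(),
                    "two_class_permutation": {
                        "r2y_intercept": round(perm.r2y_intercept, 4),
                        "q2_intercept": round(perm.q2_intercept, 4)},
                    "four_class": m4.summary(),
                }
                for feat, v in zip(scaled.columns, m2.vip):
                    vip_rows.append({"model": name, "feature": feat, "vip": v})
            (out / "opls_models.json").write_text(json.dumps(models, indent=1))
            vip_df = pd.DataFrame(vip_rows)
            _write_tsv(vip_df, out / "vip.tsv", index=False)

            high = vip_df[(vip_df["model"] == "full")
                          & (vip_df["vip"] > config.vip_threshold)]["feature"]
            cols = [c for c in high if c in raw.columns]
            if len(cols) >= 2:
                uni = univariate.univariate_screen(raw[cols], geno, control="WT",
                                                  rfc_min=config.rfc_min,
                                                  alpha=config.alpha)
                anova = univariate.anova_genotype_sex(raw[cols], geno, sex,
                                                      alpha=config.alpha)
                uni = uni.merge(anova[["feature", "q", "top_contrast"]],
                                on="feature", how="left",
                                suffixes=("", "_anova"))
                _write_tsv(uni, out / "univariate.tsv", index=False)
            else:
                _write_tsv(pd.DataFrame(), out / "univariate.tsv", index=False)
        record("opls", opls_out, params, key, skipped=not do)

    # ---- MWAS --------------------------------------------------------------
    mwas_out = [out / "mwas.tsv", out / "mwas_summary.json"]
    if "mwas" in config.stages:
        params = {"n_perm": config.n_perm_mwsl, "fwer": config.fwer,
                  "seed": config.seed, "sim": dataclasses.asdict(simcfg)}
        do, key = fresh("mwas", params, [], mwas_out)
        if do:
            design, _ = synthetic.gen_mwas_cohort(simcfg)
            feats = mwas.residualize(design.features, design.pcs,
                                     design.covariates["cohort"])
            design = mwas.MwasDesign(genotypes=design.genotypes,
                                     covariates=design.covariates,
                                     features=feats, pcs=design.pcs,
                                     class_map=design.class_map)
            res = mwas.associate(design)
            thresholds = {}
            for snp in design.genotypes.columns:
                thresholds[snp] = mwas.mwsl(design, snp,
                                            n_perm=config.n_perm_mwsl,
                                            fwer=config.fwer, seed=config.seed)
            res["mwsl"] = res["snp"].map({s: t["mwsl"] for s, t in thresholds.items()})
            res["significant"] = res["p"] < res["mwsl"]
            _write_tsv(res, out / "mwas.tsv", index=False)
            summary = mwas.summarize(res, design.class_map)
            summary["mwsl"] = {s: t["mwsl"] for s, t in thresholds.items()}
            (out / "mwas_summary.json").write_text(
                json.dumps(summary, indent=1, default=str))
        record("mwas", mwas_out, params, key, skipped=not do)

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if "report" in config.stages:
        report(out)
        manifest["stages"]["report"] = {
            "key": "report", "skipped": False, "params": {},
            "outputs": {"report.md": _sha(out / "report.md"),
                        "report.json": _sha(out / "report.json")}}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(run_dir) -> dict:
    """Render a Markdown + JSON summary of a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt manifest: {e}") from e

    data: dict = {"stages_run": sorted(manifest.get("stages", {}))}

    def load_json(name):
        p = run_dir / name
        return json.loads(p.read_text()) if p.exists() else None

    def count_rows(name):
        p = run_dir / name
        if not p.exists():
            return None
        try:
            return int(len(pd.read_csv(p, sep="\t")))
        except pd.errors.EmptyDataError:
            return 0

    de_t = run_dir / "de_transcripts.tsv"
    if de_t.exists():
        df = pd.read_csv(de_t, sep="\t")
        data["de_transcripts_called"] = int(df["called"].sum())
    de_p = run_dir / "de_proteins.tsv"
    if de_p.exists():
        df = pd.read_csv(de_p, sep="\t")
        data["de_proteins_called"] = int(df["called"].sum())
    enr = run_dir / "enrichment.tsv"
    if enr.exists():
        df = pd.read_csv(enr, sep="\t")
        data["enriched_pathways"] = int(df["significant"].sum()) if len(df) else 0
    data["signature"] = load_json("signature_counts.json")
    data["opls_models"] = load_json("opls_models.json")
    data["mwas"] = load_json("mwas_summary.json")
    data["qc_dropped_features"] = count_rows("qc_report.tsv")
    uni = run_dir / "univariate.tsv"
    if uni.exists():
        try:
            df = pd.read_csv(uni, sep="\t")
            data["univariate_significant"] = int(df["significant"].sum()) \
                if "significant" in df else 0
        except pd.errors.EmptyDataError:
            data["univariate_significant"] = 0

    (run_dir / "report.json").write_text(json.dumps(data, indent=1))

    lines = ["# Run report", ""]
    lines.append(f"Stages: {', '.join(data['stages_run'])}")
    for label, key in [("DE transcripts called", "de_transcripts_called"),
                       ("DE proteins called", "de_proteins_called"),
                       ("Significant pathways", "enriched_pathways"),
                       ("QC-dropped features", "qc_dropped_features"),
                       ("Univariate significant", "univariate_significant")]:
        v = data.get(key)
        lines.append(f"- {label}: {v if v is not None else 'no findings'}")
    if data.get("signature"):
        lines += ["", "## Predicted lipid signature",
                  "```json", json.dumps(data["signature"], indent=1), "```"]
    else:
        lines += ["", "## Predicted lipid signature", "", "no findings"]
    if data.get("opls_models"):
        lines += ["", "## OPLS-DA models (R2X/R2Y/Q2 and permutation intercepts)",
                  "```json", json.dumps(data["opls_models"], indent=1), "```"]
    else:
        lines += ["", "## OPLS-DA models", "", "no findings"]
    if data.get("mwas"):
        lines += ["", "## MWAS summary", "```json",
                  json.dumps(data["mwas"], indent=1), "```"]
    else:
        lines += ["", "## MWAS summary", "", "no findings"]
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")
    return data
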