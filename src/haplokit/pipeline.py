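"""End-to-end pipeline: simulate -> qc -> assoc -> haplotypes -> network ->
eqtl -> de -> serology, with a manifest and an exclusion log."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, de, eqtl, haplo, mjnet, qc, serology, synth, vcfio
from .config import PipelineConfig
from .synth import CohortSpec, EqtlSpec, make_default_panel

log = logging.getLogger("haplokit")


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; returns the manifest dict.

    Stage failure raises with the stage name prefixed.
    """
    all_stages = ["simulate", "qc", "assoc", "haplo", "mjnet", "eqtl", "de", "serology"]
    stages = stages or all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    _validate_inputs(config, stages)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    for stage in all_stages:
        if stage not in stages:
            continue
        fn = _STAGES[stage]
        log.info("stage %s starting", stage)
        try:
            outputs = fn(config, out_dir, state)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = outputs
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _validate_inputs(config: PipelineConfig, stages: list[str]) -> None:
    if "simulate" in stages:
        return
    if ("qc" in stages or "assoc" in stages or "haplo" in stages) and not config.vcf:
        raise ValueError("genotype stages requested without a VCF input")
    if "eqtl" in stages and not config.expression:
        raise ValueError("eqtl requested without an expression input")
    if "serology" in stages and not config.serology:
        raise ValueError("serology requested without a serology input")


def _stage_simulate(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    panel = make_default_panel(config.n_sites, config.n_hap2_diffs)
    spec = CohortSpec(
        strata=[(s, n[0], n[1]) for s, n in config.strata.items()],
        haplotype_log_or=config.haplotype_log_or,
        reference=config.reference_haplotype,
        seed=config.seed,
        mutation_rate=config.mutation_rate,
    )
    G, sheet, truth = synth.simulate_genotypes(panel, spec)
    espec = EqtlSpec(
        n_genes=config.n_genes,
        effect_per_score=config.effect_per_score,
        noise_sd=config.noise_sd,
        baseline=config.expr_baseline,
    )
    expr = synth.simulate_expression(truth, espec)
    sero = synth.simulate_serology(truth, shift={"AG1": 6.0}, n_antigens=config.n_antigens)

    vcf_path = out_dir / "genotypes.vcf"
    sheet_path = out_dir / "samples.tsv"
    expr_path = out_dir / "expression.tsv"
    sero_path = out_dir / "serology.tsv"
    truth_path = out_dir / "truth.json"
    vcfio.write_vcf(G, vcf_path)
    vcfio.write_sample_sheet(sheet, sheet_path)
    vcfio.write_matrix_tsv(expr, expr_path)
    vcfio.write_matrix_tsv(sero, sero_path)
    synth.write_truth(truth, truth_path)

    config.vcf = str(vcf_path)
    config.sample_sheet = str(sheet_path)
    config.expression = str(expr_path)
    config.serology = str(sero_path)
    state.update(G=G, sheet=sheet, truth=truth, expr=expr, sero=sero, panel=panel)
    return {
        "vcf": str(vcf_path),
        "samples": str(sheet_path),
        "expression": str(expr_path),
        "serology": str(sero_path),
        "truth": str(truth_path),
    }


def _load_genotypes(config: PipelineConfig, state: dict) -> None:
    if "G" not in state:
        G, samples = vcfio.read_genotypes(config.vcf, config.sample_sheet)
        state["G"] = G
        state["sheet"] = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in samples],
                "status": [s.status for s in samples],
                "stratum": [s.stratum for s in samples],
                "sex": [s.sex for s in samples],
                "call_rate": [s.call_rate for s in samples],
                "mean_depth": [s.mean_depth for s in samples],
            }
        )


def _load_sheet(config: PipelineConfig, state: dict) -> None:
    if "sheet" not in state:
        if not config.sample_sheet:
            raise ValueError("no sample sheet available")
        samples = vcfio.read_sample_sheet(config.sample_sheet)
        state["sheet"] = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in samples],
                "status": [s.status for s in samples],
                "stratum": [s.stratum for s in samples],
                "sex": [s.sex for s in samples],
                "call_rate": [s.call_rate for s in samples],
                "mean_depth": [s.mean_depth for s in samples],
            }
        )


def _sample_qcs(state: dict) -> list[qc.SampleQc]:
    return [
        qc.SampleQc(
            sample_id=r.sample_id,
            call_rate=float(r.call_rate),
            mean_depth=float(r.mean_depth),
            status=r.status,
            stratum=r.stratum,
            sex=r.sex,
        )
        for r in state["sheet"].itertuples()
    ]


def _stage_qc(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_genotypes(config, state)
    samples = _sample_qcs(state)
    retained, excluded = qc.filter_samples(
        samples, config.min_call_rate, config.min_depth
    )
    exclusions = [
        {"kind": "sample", "id": s.sample_id, "reason": reason}
        for s, reason in excluded
    ]
    keep_ids = [s.sample_id for s in retained]
    G = state["G"].subset_samples(keep_ids)
    stats_list = qc.variant_stats(
        G,
        retained,
        common_maf=config.common_maf,
        hwe_method=config.hwe_method,
        hwe_per_stratum=config.hwe_per_stratum,
    )
    for s in stats_list:
        if not s.excluded and s.hwe_p_controls < config.hwe_alpha:
            s.excluded = True
            s.exclusion_reason = "hwe"
    exclusions += [
        {"kind": "variant", "id": s.variant_id, "reason": s.exclusion_reason}
        for s in stats_list
        if s.excluded
    ]
    summary = qc.density_summary(
        [s for s in stats_list if not s.excluded], config.region_kb
    )

    stats_path = out_dir / "variant_stats.tsv"
    qc.variant_stats_frame(stats_list).to_csv(stats_path, sep="\t", index=False)
    excl_path = out_dir / "exclusions.json"
    with open(excl_path, "w") as fh:
        json.dump(exclusions, fh, indent=1)
    summary_path = out_dir / "density_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    state["G_qc"] = G.subset_variants(
        [s.variant_id for s in stats_list if not s.excluded]
    )
    state["samples_qc"] = retained
    state["variant_stats"] = stats_list
    return {
        "variant_stats": str(stats_path),
        "exclusions": str(excl_path),
        "density_summary": str(summary_path),
    }


def _status_strata(state: dict):
    samples = state.get("samples_qc") or _sample_qcs(state)
    by_id = {s.sample_id: s for s in samples}
    G = state.get("G_qc", state["G"])
    status = np.array([by_id[s].status == "case" for s in G.samples])
    strata = np.array([by_id[s].stratum for s in G.samples])
    return G, status, strata


def _stage_assoc(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_genotypes(config, state)
    G, status, strata = _status_strata(state)
    gc_subset = None
    if config.gc_common_only and "variant_stats" in state:
        gc_subset = np.array(
            [
                s.variant_id
                for s in state["variant_stats"]
                if not s.excluded and s.freq_class == "common"
            ]
        )
        if gc_subset.size == 0:
            gc_subset = None
    results, inflation = assoc.allelic_scan(G, status, gc_variants=gc_subset)
    cmh_results = assoc.cmh_scan(G, status, strata)
    frame = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "case_alt": [r.table[0] for r in results],
            "case_ref": [r.table[1] for r in results],
            "ctrl_alt": [r.table[2] for r in results],
            "ctrl_ref": [r.table[3] for r in results],
            "or": [r.or_ for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "chi2": [r.chi2 for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_gc": [r.p_gc for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "or_mh": [c.or_mh for c in cmh_results],
            "chi2_cmh": [c.chi2_cmh for c in cmh_results],
            "p_cmh": [c.p for c in cmh_results],
        }
    )
    path = out_dir / "assoc.tsv"
    frame.to_csv(path, sep="\t", index=False)
    outputs = {"assoc": str(path), "lambda": inflation.lambda_}

    peak = config.peak_variant or frame.loc[frame["p_raw"].idxmin(), "variant_id"]
    state["peak_variant"] = peak
    cond = assoc.conditional_scan(G, status, peak)
    cond_frame = pd.DataFrame(
        {
            "variant_id": [c.id for c in cond],
            "or_mh": [c.or_mh for c in cond],
            "chi2_cmh": [c.chi2_cmh for c in cond],
            "p": [c.p for c in cond],
            "testable": [c.testable for c in cond],
        }
    )
    cond_path = out_dir / "conditional.tsv"
    cond_frame.to_csv(cond_path, sep="\t", index=False)
    outputs["conditional"] = str(cond_path)
    outputs["peak_variant"] = str(peak)
    return outputs


def _stage_haplo(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_genotypes(config, state)
    G, status, strata = _status_strata(state)
    peak = state.get("peak_variant") or config.peak_variant or G.variants[0]
    tags = haplo.select_tag_set(G, peak, threshold=config.tag_dprime)
    Gt = G.subset_variants(tags)

    tag_rows = []
    for v in tags:
        ld = haplo.ld_from_genotypes(G, peak, v)
        tag_rows.append(
            {"variant_id": v, "Dprime": ld.Dprime, "r2": ld.r2, "peak": peak}
        )
    tags_path = out_dir / "tags.tsv"
    pd.DataFrame(tag_rows).to_csv(tags_path, sep="\t", index=False)

    table = haplo.em_haplotype_frequencies(Gt)
    table_path = out_dir / "haplotypes.tsv"
    pd.DataFrame(
        {
            "haplotype": table.haplotypes,
            "frequency": table.freqs,
            "expected_count": table.expected_counts,
        }
    ).to_csv(table_path, sep="\t", index=False)

    hap_results = haplo.haplotype_assoc(Gt, status, strata)
    rows = []
    for hap, (cmh_res, audit) in hap_results.items():
        rows.append(
            {
                "haplotype": hap,
                "or_mh": cmh_res.or_mh,
                "chi2_cmh": cmh_res.chi2_cmh,
                "p": cmh_res.p,
                "strata": json.dumps(audit),
            }
        )
    assoc_path = out_dir / "haplotype_assoc.tsv"
    pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False)

    panel = state.get("panel") or make_default_panel(len(tags) or 1, max(1, min(config.n_hap2_diffs, len(tags) or 1)))
    panel_vectors = {lab: panel.vector(lab) for lab in panel.labels}
    assignments = haplo.assign_diplotypes(Gt, table, panel_vectors=panel_vectors)
    status_map = dict(zip(G.samples, status))
    try:
        dose = haplo.diplotype_dose(assignments, status_map)
        trend = dose["trend"]
    except ValueError:
        dose, trend = None, {"slope": float("nan"), "p": float("nan")}
    state["assignments"] = assignments
    state["haplotype_table"] = table
    state["tags"] = tags

    dose_path = out_dir / "diplotype_dose.json"
    payload = {"trend": trend}
    if dose is not None:
        payload["per_diplotype"] = {
            "/".join(pair): {"or": r.or_, "ci95": list(r.ci95), "p": r.p_raw}
            for pair, r in dose["per_diplotype"].items()
        }
        payload["counts"] = {
            "/".join(pair): c for pair, c in dose["counts"].items()
        }
    with open(dose_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {
        "tags": str(tags_path),
        "haplotypes": str(table_path),
        "haplotype_assoc": str(assoc_path),
        "diplotype_dose": str(dose_path),
    }


def _stage_mjnet(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    table = state.get("haplotype_table")
    if table is None:
        raise ValueError("mjnet requires the haplo stage")
    G, status, _ = _status_strata(state)
    Gt = G.subset_variants(state["tags"])
    haps = {h: tuple(int(c) for c in h) for h in table.haplotypes}
    # case/control chromosome counts from per-group EM expectations
    counts: dict[str, list[int]] = {h: [0, 0] for h in haps}
    for k, mask in ((0, status), (1, ~status)):
        sub = Gt.subset_samples([s for s, m in zip(Gt.samples, mask) if m])
        t = haplo.em_haplotype_frequencies(sub)
        for h, exp in zip(t.haplotypes, t.expected_counts):
            if h in counts:
                counts[h][k] = int(round(exp))
    counts_t = {h: tuple(c) for h, c in counts.items()}
    graph = mjnet.build_mj_network(haps, counts=counts_t)
    mjnet.annotate_nodes(graph, counts_t)
    graphml_path = out_dir / "network.graphml"
    dot_path = out_dir / "network.dot"
    mjnet.write_graphml(graph, graphml_path)
    mjnet.write_dot(graph, dot_path)
    return {"graphml": str(graphml_path), "dot": str(dot_path)}


def _stage_eqtl(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_genotypes(config, state)
    expr = state.get("expr")
    if expr is None:
        expr = vcfio.read_matrix_tsv(config.expression)
        state["expr"] = expr
    G = state.get("G_qc", state["G"])
    common = [s for s in G.samples if s in expr.columns]
    expr = expr[common]
    sheet = state["sheet"].set_index("sample_id").loc[common]
    normalized, flagged = eqtl.normalize_expression(
        expr, covariates=sheet[["sex", "stratum"]]
    )
    peak = state.get("peak_variant") or config.peak_variant or G.variants[0]
    dose = G.subset_samples(common).column(peak).astype(float)
    rows = []
    for gene in normalized.index:
        res = eqtl.cis_eqtl(normalized.loc[gene], dose, gene=gene, variant=peak)
        rows.append(
            {
                "gene": gene,
                "variant": peak,
                "beta": res.beta,
                "t_stat": res.t_stat,
                "p": res.p,
                "n": res.n,
            }
        )
    path = out_dir / "eqtl.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"eqtl": str(path), "constant_genes": flagged}


def _stage_de(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_sheet(config, state)
    expr = state.get("expr")
    if expr is None:
        expr = vcfio.read_matrix_tsv(config.expression)
        state["expr"] = expr
    sheet = state["sheet"].set_index("sample_id")
    case_ids = [s for s in expr.columns if sheet.loc[s, "status"] == "case"]
    ctrl_ids = [s for s in expr.columns if sheet.loc[s, "status"] == "control"]
    cfg = de.DeConfig(
        background_rpkm=config.de_background_rpkm,
        t_alpha=config.de_t_alpha,
        assoc_alpha=config.de_assoc_alpha,
        min_fold=config.de_min_fold,
        f_alpha=config.de_f_alpha,
    )
    results, ref = de.run_de(expr[case_ids], expr[ctrl_ids], cfg)
    path = out_dir / "de.tsv"
    de.de_frame(results).to_csv(path, sep="\t", index=False)
    return {
        "de": str(path),
        "n_reference_genes": len(ref.reference_genes),
        "n_passed": sum(r.passed for r in results),
    }


def _stage_serology(config: PipelineConfig, out_dir: Path, state: dict) -> dict:
    _load_sheet(config, state)
    sero = state.get("sero")
    if sero is None:
        sero = vcfio.read_matrix_tsv(config.serology)
        state["sero"] = sero
    normalized = serology.normalize_nfi(sero)
    assignments = state.get("assignments")
    if assignments:
        group = {}
        for a in assignments:
            if a.pair == ("HAP3", "HAP3"):
                group[a.sample_id] = "risk"
            elif "HAP3" in a.pair:
                group[a.sample_id] = "het"
            else:
                group[a.sample_id] = "protective"
        groups = pd.Series(group)
    else:
        sheet = state["sheet"].set_index("sample_id")
        groups = sheet["status"].map({"case": "risk", "control": "protective"})
    results, sample_cmp = serology.group_enrichment(
        normalized, groups, fold_threshold=config.serology_fold_threshold
    )
    path = out_dir / "serology.tsv"
    serology.enrichment_frame(results).to_csv(path, sep="\t", index=False)
    order = serology.antigen_cluster_order(normalized)
    order_path = out_dir / "antigen_order.txt"
    Path(order_path).write_text("\n".join(order) + "\n")
    return {
        "serology": str(path),
        "antigen_order": str(order_path),
        "sample_comparison": sample_cmp,
    }


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assoc": _stage_assoc,
    "haplo": _stage_haplo,
    "mjnet": _stage_mjnet,
    "eqtl": _stage_eqtl,
    "de": _stage_de,
    "serology": _stage_serology,
}
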