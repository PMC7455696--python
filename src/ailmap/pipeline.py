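"""Pipeline stages tying the modules into the end-to-end workflow.

Each stage reads its inputs from the run's output directory (written by an
earlier stage or supplied externally), validates them before writing
anything, logs filter attrition at INFO, and leaves a
``metadata_<stage>.json`` recording parameters and seed so reruns are
auditable.  ``run_all`` chains every stage on one config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, haplo, ibdmap, markers, popgen, sharing, sim, vcfio
from .genotypes import concat_samples

log = logging.getLogger(__name__)


def _out(cfg) -> Path:
    p = Path(cfg["out_dir"])
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_meta(cfg: dict, stage: str, info: dict) -> None:
    meta = {"stage": stage, "seed": cfg["seed"], **info}
    with open(_out(cfg) / f"metadata_{stage}.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _gmap(cfg) -> sim.GeneticMap:
    m = cfg["map"]
    return sim.GeneticMap(m["rate_cM_per_Mb"], m["region_start_bp"], m["region_end_bp"])


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_covariates(pheno: pd.DataFrame, names: list[str]) -> np.ndarray | None:
    """Covariate design from the phenotype table: sex as 0/1, batch as
    dummy columns (first level dropped)."""
    cols = []
    if "sex" in names:
        cols.append((pheno["sex"] == "M").astype(float).values)
    if "batch" in names:
        levels = sorted(pheno["batch"].unique())[1:]
        for lev in levels:
            cols.append((pheno["batch"] == lev).astype(float).values)
    extra = [n for n in names if n not in ("sex", "batch")]
    for n in extra:
        cols.append(pheno[n].astype(float).values)
    return np.column_stack(cols) if cols else None


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def stage_simulate(cfg: dict) -> dict:
    """Simulate founders, the AIL, phenotypes and the multi-breed panel."""
    out = _out(cfg)
    gmap = _gmap(cfg)
    s = cfg["sim"]
    positions = sim.snp_grid(gmap, s["grid_spacing_bp"])
    rng_pool, rng_founders, rng_ail, rng_pheno, rng_panel = _child_seeds(cfg["seed"], 5)
    q_intervals = [tuple(iv) for iv in s["q_intervals"]]
    poolA, poolB = sim.make_divergent_pools(
        positions, rng_pool,
        n_hap_A=s["n_hap_per_pool"][0], n_hap_B=s["n_hap_per_pool"][1],
        frac_diagnostic=s["frac_diagnostic"], q_private_intervals=q_intervals,
        qtl_positions=[l["position_bp"] for l in s["qtl"]["loci"]
                       if l.get("high_allele", 1) == 1])
    founders = sim.make_founders(poolA, poolB, s["n_founders"][0], s["n_founders"][1],
                                 rng_founders, gmap)
    pedigree = sim.simulate_ail(founders, s["generation_sizes"], gmap, positions, rng_ail)
    final = pedigree[max(pedigree)]
    q = s["qtl"]
    arch = sim.QTLArchitecture(
        loci=[sim.QTLLocus(l["position_bp"], l["effect_g"], l.get("high_allele", 1))
              for l in q["loci"]],
        baseline_g=q["baseline_g"], sex_effect_g=q["sex_effect_g"],
        batch_effects_g=tuple(q["batch_effects_g"]), residual_sd_g=q["residual_sd_g"])
    pheno = sim.simulate_phenotypes(final, arch, positions, rng_pheno)
    breeds = [sim.BreedSpec(b["name"], b["group"], b["n"], b["q_carrier_freq"])
              for b in s["panel"]["breeds"]]
    panel, groups = sim.simulate_breed_panel(poolA, poolB, breeds, q_intervals,
                                             positions, rng_panel)

    f0 = sim.pedigree_to_genotypes(founders, positions)
    f9 = sim.pedigree_to_genotypes(final, positions)
    vcfio.write_vcf(f0, out / "f0.vcf")
    vcfio.write_vcf(f9, out / "final_generation.vcf")
    vcfio.write_vcf(panel, out / "panel.vcf")
    vcfio.write_phenotypes(pheno, out / "phenotypes.tsv")
    pd.DataFrame({"sample": [f.id for f in founders],
                  "line": [f.paintings[0][0][2] for f in founders],
                  "role": ["A" if f.paintings[0][0][2] == poolA.label else "B"
                           for f in founders]}
                 ).to_csv(out / "founder_labels.tsv", sep="\t", index=False)
    groups.to_csv(out / "panel_groups.tsv", sep="\t", index=False)
    vcfio.write_paintings(sim.paintings_table(final), out / "truth_paintings.tsv")
    truth = {"qtl_positions": [l["position_bp"] for l in q["loci"]],
             "qtl_effects_g": [l["effect_g"] for l in q["loci"]],
             "q_intervals": [list(iv) for iv in q_intervals],
             "founder_lines": [poolA.label, poolB.label]}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    log.info("simulate: %d founders, final generation n=%d, panel n=%d, %d sites",
             len(founders), len(final), panel.n_samples, positions.size)
    _write_meta(cfg, "simulate", {"n_sites": int(positions.size),
                                  "n_final": len(final), "n_panel": panel.n_samples})
    return {"f0": f0, "f9": f9, "panel": panel, "pheno": pheno, "truth": truth}


def stage_select_markers(cfg: dict) -> dict:
    """Founder dAF differentials, tiered selection, thresholds."""
    out = _out(cfg)
    for name in ("f0.vcf", "final_generation.vcf", "founder_labels.tsv"):
        vcfio.ensure_exists(out / name)
    f0 = vcfio.read_vcf(out / "f0.vcf")
    labels = pd.read_csv(out / "founder_labels.tsv", sep="\t")
    idxA = f0.sample_index(labels.loc[labels["role"] == "A", "sample"])
    idxB = f0.sample_index(labels.loc[labels["role"] == "B", "sample"])
    diffs = markers.marker_diffs(f0.take_samples(idxA), f0.take_samples(idxB))
    mcfg = cfg["markers"]
    sel = markers.select_informative(diffs, mcfg["tier1"], mcfg["tier2"],
                                     mcfg["annot_tier"], mcfg["spacing_bp"])
    sel.table().to_csv(out / "markers.tsv", sep="\t", index=False)
    key_rows = [(m.site_id, m.position + 1, 1 if m.af_popA >= m.af_popB else 0)
                for m in sel.tier1]
    pd.DataFrame(key_rows, columns=["site_id", "position", "allele_A"]
                 ).to_csv(out / "founder_key.tsv", sep="\t", index=False)
    f9 = vcfio.read_vcf(out / "final_generation.vcf")
    n_indep = markers.n_independent_markers(f9, mcfg["ld_r2_max"])
    thresholds = {f"alpha_{a}": markers.bonferroni_threshold(a, n_indep)
                  for a in mcfg["alphas"]}
    with open(out / "thresholds.json", "w") as fh:
        json.dump({"n_independent": n_indep, **thresholds}, fh, indent=2)
    log.info("select-markers: %d diffs -> %d tier1, %d tier2 (spaced), %d annotated; "
             "n_independent=%d", len(diffs), len(sel.tier1), len(sel.tier2),
             len(sel.annotated), n_indep)
    _write_meta(cfg, "select_markers", {"n_tier1": len(sel.tier1),
                                        "n_tier2": len(sel.tier2),
                                        "n_independent": n_indep})
    return {"selection": sel, "n_independent": n_indep, "thresholds": thresholds}


def stage_scan_gwas(cfg: dict) -> dict:
    """Mixed-model association scan of the final generation."""
    out = _out(cfg)
    for name in ("final_generation.vcf", "phenotypes.tsv"):
        vcfio.ensure_exists(out / name)
    f9 = vcfio.read_vcf(out / "final_generation.vcf")
    pheno = vcfio.read_phenotypes(out / "phenotypes.tsv").set_index("id").loc[f9.samples].reset_index()
    y = pheno["phenotype_g"].values
    cov = build_covariates(pheno, cfg["assoc"]["covariates"])
    K = assoc.grm(f9.dosages())
    vc = assoc.fit_null(y, cov, K)
    table = assoc.assoc_scan(f9, y, cov, vc, K)
    table.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
    assoc.qq_table(table["p"].dropna().values).to_csv(out / "qq.tsv", sep="\t",
                                                      index=False, float_format="%.6g")
    log.info("scan-gwas: n=%d, %d SNPs, Vg=%.1f Ve=%.1f h2=%.3f",
             len(y), f9.n_sites, vc.Vg, vc.Ve, vc.heritability)
    _write_meta(cfg, "scan_gwas", {"Vg": vc.Vg, "Ve": vc.Ve,
                                   "heritability": vc.heritability})
    return {"table": table, "vc": vc, "K": K}


def stage_ibd_map(cfg: dict) -> dict:
    """Paint founder origin, call blocks, test blocks against the trait."""
    out = _out(cfg)
    for name in ("final_generation.vcf", "founder_key.tsv", "phenotypes.tsv"):
        vcfio.ensure_exists(out / name)
    f9 = vcfio.read_vcf(out / "final_generation.vcf")
    key = vcfio.read_founder_key(out / "founder_key.tsv")
    pos_idx = {int(p): i for i, p in enumerate(f9.positions)}
    idx = [pos_idx[p] for p in key["position"] if p in pos_idx]
    sub = f9.take_sites(idx)
    gmap = _gmap(cfg)
    ps = ibdmap.paint(sub, key["allele_A"].values[: sub.n_sites],
                      region=(gmap.region_start_bp, gmap.region_end_bp),
                      min_support=cfg["ibd"]["min_support"])
    bs = ibdmap.call_blocks(ps)
    ps.table(f9.chrom).to_csv(out / "paintings.tsv", sep="\t", index=False)
    bs.class_table().to_csv(out / "blocks.tsv", sep="\t")
    pheno = vcfio.read_phenotypes(out / "phenotypes.tsv").set_index("id")["phenotype_g"]
    tests = []
    for b in range(len(bs.blocks)):
        t = ibdmap.block_ttest(bs, pheno, b)
        tests.append((b + 1, bs.blocks[b][0], bs.blocks[b][1], t.p_value,
                      t.mean_A, t.mean_B, t.n_A, t.n_B))
    pd.DataFrame(tests, columns=["block", "start", "end", "p", "mean_A", "mean_B",
                                 "n_A", "n_B"]
                 ).to_csv(out / "block_tests.tsv", sep="\t", index=False,
                          float_format="%.6g")
    n_rec = int(bs.recombinant.sum())
    log.info("ibd-map: %d markers, %d breakpoints, %d blocks, %d/%d recombinant",
             sub.n_sites, len(bs.breakpoints), len(bs.blocks), n_rec, len(bs.ids))
    _write_meta(cfg, "ibd_map", {"n_markers": sub.n_sites,
                                 "n_breakpoints": len(bs.breakpoints),
                                 "n_recombinant": n_rec})
    return {"paintings": ps, "blocks": bs}


def stage_haplo_fit(cfg: dict) -> dict:
    """Backward elimination to BESNPs, then haplotype substitution effects."""
    out = _out(cfg)
    for name in ("final_generation.vcf", "phenotypes.tsv", "assoc.tsv"):
        vcfio.ensure_exists(out / name)
    f9 = vcfio.read_vcf(out / "final_generation.vcf")
    pheno = vcfio.read_phenotypes(out / "phenotypes.tsv").set_index("id").loc[f9.samples].reset_index()
    y = pheno["phenotype_g"].values
    cov = build_covariates(pheno, ["sex"])
    table = pd.read_csv(out / "assoc.tsv", sep="\t")
    hcfg = cfg["haplo"]
    cand = table.dropna(subset=["p"]).nsmallest(hcfg["n_tag_snps"], "p")
    cand = cand.sort_values("pos")
    pos0 = cand["pos"].values - 1
    site_idx = np.searchsorted(f9.positions, pos0)
    G = np.nan_to_num(f9.dosages()[:, site_idx])
    elim = haplo.backward_elimination(y, G, list(cand["id"]), cand["pos"].values,
                                      covariates=cov, fdr=hcfg["fdr"])
    elim.audit.to_csv(out / "elimination_audit.tsv", sep="\t", index=False)
    pd.DataFrame({"id": elim.retained}).to_csv(out / "besnps.tsv", sep="\t", index=False)
    kept = cand[cand["id"].isin(elim.retained)]
    if len(kept) == 0:
        log.warning("haplo-fit: no BESNPs retained; skipping haplotype model")
        _write_meta(cfg, "haplo_fit", {"n_candidates": len(cand), "n_besnps": 0})
        return {"elimination": elim, "model": None}
    kept_idx = np.searchsorted(f9.positions, kept["pos"].values - 1)
    sub = f9.take_sites(kept_idx)
    if sub.phased:
        pairs = [(tuple(int(a) for a in sub.haplotypes[i, :, 0]),
                  tuple(int(a) for a in sub.haplotypes[i, :, 1]))
                 for i in range(sub.n_samples)]
        haps, freqs, Z = haplo.phased_dosage_matrix(pairs)
    else:
        em = haplo.em_haplotype_freqs(np.nan_to_num(sub.dosages()).astype(int))
        haps, freqs, Z = em.haplotypes, em.frequencies, haplo.haplotype_dosage_matrix(em)
    major, freqs_p, Zp = haplo.group_rare(freqs, Z, hcfg["min_freq"])
    labels = ["".join(map(str, haps[i])) for i in major]
    if Zp.shape[1] > major.size:
        labels.append("Other")
    model = haplo.substitution_effects(y, Zp, cov, freqs_p, labels)
    model.table().to_csv(out / "haplotype_effects.tsv", sep="\t", index=False,
                         float_format="%.6g")
    log.info("haplo-fit: %d candidates -> %d BESNPs -> %d haplotypes "
             "(%d major + %s)", len(cand), len(kept), len(freqs),
             major.size, "Other" if Zp.shape[1] > major.size else "no Other")
    _write_meta(cfg, "haplo_fit", {"n_candidates": len(cand),
                                   "n_besnps": len(kept),
                                   "n_haplotypes": int(len(freqs)),
                                   "n_major": int(major.size)})
    return {"elimination": elim, "model": model}


def stage_share_scan(cfg: dict) -> dict:
    """Multi-breed Q-region scan; founders of the high line define Q."""
    out = _out(cfg)
    for name in ("panel.vcf", "panel_groups.tsv", "f0.vcf", "founder_labels.tsv"):
        vcfio.ensure_exists(out / name)
    panel = vcfio.read_vcf(out / "panel.vcf")
    groups = pd.read_csv(out / "panel_groups.tsv", sep="\t")
    f0 = vcfio.read_vcf(out / "f0.vcf")
    labels = pd.read_csv(out / "founder_labels.tsv", sep="\t")
    refs = labels.loc[labels["role"] == "A", "sample"]
    ref = f0.take_samples(f0.sample_index(refs))
    ref.samples = [f"ref_{s}" for s in ref.samples]
    combined = concat_samples(panel, ref)
    grouping = pd.Series(
        list(groups["group"]) + ["ref"] * ref.n_samples,
        index=list(groups["sample"]) + list(ref.samples))
    scfg = cfg["sharing"]
    region = tuple(scfg["sub_region"]) if scfg["sub_region"] else None
    table, regions = sharing.sharing_scan(combined, grouping, "ref",
                                          bin_bp=scfg["bin_bp"],
                                          threshold=scfg["threshold"],
                                          region=region)
    vcfio.write_scan(table, out / "sharing_bins.tsv")
    vcfio.write_bed([(r.start, r.end) for r in regions], out / "q_regions.bed",
                    [r.name for r in regions], chrom=panel.chrom)
    log.info("share-scan: %d bins, %d Q regions (%s)", len(table), len(regions),
             ", ".join(f"{r.name}:{r.length_bp}bp" for r in regions) or "none")
    _write_meta(cfg, "share_scan", {"n_bins": len(table), "n_q_regions": len(regions)})
    return {"table": table, "regions": regions}


def stage_sweep_stats(cfg: dict) -> dict:
    """Diversity/differentiation scans of the founder lines."""
    out = _out(cfg)
    for name in ("f0.vcf", "founder_labels.tsv"):
        vcfio.ensure_exists(out / name)
    f0 = vcfio.read_vcf(out / "f0.vcf")
    labels = pd.read_csv(out / "founder_labels.tsv", sep="\t")
    roles = {}
    for role in ("A", "B"):
        sub = labels.loc[labels["role"] == role]
        roles[role] = (sub["line"].iloc[0],
                       f0.take_samples(f0.sample_index(sub["sample"])))
    lines = [roles["A"][0], roles["B"][0]]
    pops = {ln: gm for ln, gm in roles.values()}
    pcfg = cfg["popgen"]
    gmap = _gmap(cfg)
    region = (gmap.region_start_bp, gmap.region_end_bp)
    results = {}
    for ln, gm in pops.items():
        scans = [popgen.pi_scan(gm, pcfg["pi_window_bp"], pcfg["pi_step_bp"], region),
                 popgen.tajimas_d(gm, pcfg["tajd_bin_bp"], region),
                 popgen.hap_diversity(gm, pcfg["hap_div_bin_bp"], region)]
        combined = pd.concat(scans, ignore_index=True)
        vcfio.write_scan(combined, out / f"sweep_{ln}.tsv")
        results[ln] = combined
    fst_table = popgen.fst(pops[lines[0]], pops[lines[1]],
                           window_bp=pcfg["fst_window_bp"], region=region)
    vcfio.write_scan(fst_table, out / "fst.tsv")
    step = max(1, int(pcfg["xpehh_core_step"]))
    sub_idx = np.arange(0, f0.n_sites, step)
    xp = popgen.xpehh_scan(pops[lines[0]].take_sites(sub_idx),
                           pops[lines[1]].take_sites(sub_idx), gmap)
    vcfio.write_scan(xp, out / "xpehh.tsv")
    log.info("sweep-stats: wrote per-line diversity scans, Fst and XP-EHH (%d cores)",
             len(xp))
    _write_meta(cfg, "sweep_stats", {"n_xpehh_cores": int(len(xp))})
    results.update({"fst": fst_table, "xpehh": xp})
    return results


STAGES = {
    "simulate": stage_simulate,
    "select-markers": stage_select_markers,
    "scan-gwas": stage_scan_gwas,
    "ibd-map": stage_ibd_map,
    "haplo-fit": stage_haplo_fit,
    "share-scan": stage_share_scan,
    "sweep-stats": stage_sweep_stats,
}


def run_all(cfg: dict) -> dict:
    """Chain every stage on one config."""
    results = {}
    for name, fn in STAGES.items():
        log.info("=== stage %s ===", name)
        results[name] = fn(cfg)
    _write_meta(cfg, "run_all", {"stages": list(STAGES)})
    return results
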