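"""End-to-end orchestration of the analysis stages on synthetic data.

``run_pipeline`` executes simulate -> ascertain -> pseudohaploid and the
toggled analysis stages (ROH/diversity, D/f3, kinship/IBS-NJ, selection
scan, mtDNA), writing per-stage artifacts and a JSON manifest holding
every parameter, seed, and headline number needed to reproduce the run.
Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diversity, fstats, io, relatedness, scan, simdata
from .genotypes import ascertain_panel, population_frequencies, pseudohaploid_call
from .uniparental import estimate_contamination, mean_pairwise_differences

logger = logging.getLogger("hircus")

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "n_sites",
    "chrom_lengths",
    "tree",
    "admixture_edges",
    "n_individuals",
    "coverage",
    "base_error",
    "roh_tracts",
    "het_rate",
    "roh",
    "fstats",
    "relatedness",
    "scan",
    "mt",
}

_DEFAULT_STAGES = ("simulate", "ascertain", "pseudohaploid", "roh", "fstats",
                   "relatedness", "mt")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("tree", "chrom_lengths", "n_individuals"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")


def _build_sim_config(cfg: dict, seed: int) -> simdata.SimConfig:
    tree = tuple(
        simdata.PopulationNode(n["name"], n.get("parent"), float(n.get("drift", 0.0)))
        for n in cfg["tree"]
    )
    tracts = {
        sample: tuple((t["chrom"], int(t["start"]), int(t["end"])) for t in entries)
        for sample, entries in (cfg.get("roh_tracts") or {}).items()
    }
    return simdata.SimConfig(
        tree=tree,
        n_sites=int(cfg.get("n_sites", 50_000)),
        n_individuals={k: int(v) for k, v in cfg["n_individuals"].items()},
        chrom_lengths={k: int(v) for k, v in cfg["chrom_lengths"].items()},
        coverage=float(cfg.get("coverage", 2.0)),
        base_error=float(cfg.get("base_error", 2e-5)),
        admixture_edges=tuple(
            (e["source"], e["dest"], float(e["proportion"]))
            for e in (cfg.get("admixture_edges") or [])
        ),
        roh_tracts=tracts,
        seed=seed,
    )


def run_pipeline(cfg: dict, out_dir=None, seed: int | None = None) -> dict:
    """Run the toggled stages; returns (and writes) the manifest."""
    validate_config(cfg)
    t0 = time.time()
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or cfg.get("out_dir", "hircus_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.get("stages") or _DEFAULT_STAGES)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "results": {},
        "artifacts": {},
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))

    current = None
    try:
        current = "simulate"
        sim_cfg = _build_sim_config(cfg, seed)
        truth = simdata.simulate_world(sim_cfg)
        (out / "sim_truth.json").write_text(truth.to_json())
        manifest["results"]["simulate"] = {
            "n_sites": int(truth.pos.size),
            "n_samples": len(truth.genotypes),
        }

        current = "ascertain"
        samples = list(truth.genotypes)
        geno = np.vstack([truth.genotypes[s] for s in samples])
        sites = _sites_frame(truth)
        pops = [truth.sample_pop[s] for s in samples]
        panel = ascertain_panel(sites, geno, pops)
        panel.to_tsv(out / "panel.tsv")
        manifest["results"]["ascertain"] = {"panel_sites": len(panel)}
        manifest["artifacts"]["panel"] = "panel.tsv"

        current = "pseudohaploid"
        panel_idx = sites.reset_index().merge(
            panel.sites[["chrom", "pos"]], on=["chrom", "pos"]
        )["index"].to_numpy()
        pileups = {}
        for s in samples:
            ref_c, alt_c = simdata.simulate_reads(
                truth.genotypes[s][panel_idx],
                sim_cfg.coverage,
                sim_cfg.base_error,
                rng,
            )
            pileups[s] = pd.DataFrame(
                {
                    "chrom": panel.sites["chrom"],
                    "pos": panel.sites["pos"],
                    "ref_count": ref_c,
                    "alt_count": alt_c,
                }
            )
        matrix = pseudohaploid_call(pileups, panel, rng)
        manifest["results"]["pseudohaploid"] = {
            "mean_missing_rate": float(np.mean(matrix.missing_rate))
        }

        if "roh" in stages:
            current = "roh"
            manifest["results"]["roh"] = _stage_roh(cfg, rng, out, manifest)
        if "fstats" in stages:
            current = "fstats"
            manifest["results"]["fstats"] = _stage_fstats(
                truth, matrix, pops, out
            )
        if "relatedness" in stages:
            current = "relatedness"
            manifest["results"]["relatedness"] = _stage_relatedness(
                matrix, rng, out, cfg
            )
        if "scan" in stages:
            current = "scan"
            manifest["results"]["scan"] = _stage_scan(truth, cfg, out)
        if "mt" in stages:
            current = "mt"
            manifest["results"]["mt"] = _stage_mt(cfg, rng, out)
    except Exception as exc:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["manifest_hash_input"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _sites_frame(truth):
    return pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.pos,
            "ref": simdata.REF_BASE,
            "alt": simdata.ALT_BASE,
        }
    )


def _stage_roh(cfg, rng, out, manifest):
    roh_cfg = cfg.get("roh") or {}
    chrom_lengths = {k: int(v) for k, v in cfg["chrom_lengths"].items()}
    het_rate = float(cfg.get("het_rate", 1e-3))
    base_error = float(cfg.get("base_error", 2e-5))
    tracts = {
        s: [(t["chrom"], int(t["start"]), int(t["end"])) for t in entries]
        for s, entries in (cfg.get("roh_tracts") or {}).items()
    }
    x_len = int(roh_cfg.get("x_length", 120_000_000))
    n_males = int(roh_cfg.get("n_males", 3))
    male_tracks = [
        simdata.simulate_window_track(
            {"X": x_len}, 0.0, base_error, rng, haploid=True
        )
        for _ in range(n_males)
    ]
    nonpar = ("X", int(roh_cfg.get("par_bp", 7_000_000)) + 1, x_len)
    tau = diversity.calibrate_threshold(male_tracks, nonpar)
    results = {"threshold": tau, "samples": {}}
    for sample in tracts or {"background": []}:
        track = simdata.simulate_window_track(
            chrom_lengths, het_rate, base_error, rng,
            roh_tracts=tracts.get(sample, []),
        )
        calls = diversity.call_roh(track, tau, sample=sample)
        calls.to_bed(out / f"roh_{sample}.bed")
        results["samples"][sample] = {
            "f_roh_5mb": calls.f_roh_5mb,
            "n_roh": int(len(calls.intervals)),
        }
    return results


def _stage_fstats(truth, matrix, pops, out):
    freq = population_frequencies(matrix.calls, pops)
    pivot = freq.pivot(index="site", columns="pop", values="freq")
    pop_names = list(pivot.columns)
    if len(pop_names) < 4:
        return {"skipped": "need >= 4 populations for D"}
    chrom = matrix.panel.sites["chrom"].to_numpy()
    pos = matrix.panel.sites["pos"].to_numpy()
    h1, h2, h3, h4 = pop_names[:4]
    res = fstats.d_statistic(
        pivot[h1].to_numpy(), pivot[h2].to_numpy(),
        pivot[h3].to_numpy(), pivot[h4].to_numpy(),
        chrom, pos, pops=(h1, h2, h3, h4),
    )
    f3 = fstats.outgroup_f3(
        pivot[h4].to_numpy(), pivot[h1].to_numpy(), pivot[h2].to_numpy(),
        chrom, pos, pops=(h4, h1, h2),
    )
    return {
        "d": {"pops": list(res.pops), "d": res.d, "z": res.z},
        "f3": {"pops": list(f3.pops), "f3": f3.f3, "z": f3.z},
    }


def _stage_relatedness(matrix, rng, out, cfg):
    rel_cfg = cfg.get("relatedness") or {}
    mism = relatedness.pairwise_mismatch(matrix)
    kin = relatedness.kinship_pihat(mism)
    mism.to_csv(out / "kinship.tsv", sep="\t", index=False)
    tree = relatedness.bootstrap_tree(
        matrix, rng,
        n_reps=int(rel_cfg.get("bootstraps", 50)),
        block_bp=int(rel_cfg.get("block_bp", 5_000_000)),
    )
    (out / "ibs_nj.nwk").write_text(tree.newick() + "\n")
    return {
        "mean_pi_hat": float(np.mean([k.pi_hat for k in kin])),
        "n_pairs": len(kin),
        "min_support": min(tree.supports.values()) if tree.supports else None,
    }


def _stage_scan(truth, cfg, out):
    scan_cfg = cfg.get("scan") or {}
    target = scan_cfg.get("target") or list(truth.pop_freqs)[-1]
    reference = scan_cfg.get("reference") or list(truth.pop_freqs)[0]
    n_chrom = 2 * truth.config.n_individuals.get(target, 5)
    sites = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.pos,
            f"{target}_freq": truth.pop_freqs[target],
            f"{target}_n": max(n_chrom, 2),
            f"{reference}_freq": truth.pop_freqs[reference],
            f"{reference}_n": max(
                2 * truth.config.n_individuals.get(reference, 5), 2
            ),
        }
    )
    table = scan.windowed_scan(
        sites,
        truth.config.chrom_lengths,
        target,
        reference,
        window_bp=int(scan_cfg.get("window_bp", 50_000)),
        step_bp=int(scan_cfg.get("step_bp", 10_000)),
        min_snps=int(scan_cfg.get("min_snps", 10)),
    )
    if table.empty:
        return {"skipped": "no windows with enough SNPs"}
    flagged, regions = scan.outlier_filter(table)
    io.write_bed(out / "scan_outliers.bed", regions) if not regions.empty else None
    return {
        "n_windows": int(len(table)),
        "n_outlier_windows": int(flagged["outlier_flag"].sum()),
        "n_regions": int(len(regions)),
        "mean_fst": float(table["fst"].mean()),
    }


def _stage_mt(cfg, rng, out):
    mt_cfg = cfg.get("mt") or {}
    L = int(mt_cfg.get("length", 2000))
    c_true = float(mt_cfg.get("contamination", 0.02))
    n_variants = int(mt_cfg.get("n_variants", 50))
    endo = "".join(rng.choice(list("ACGT"), size=L))
    var_pos = np.sort(rng.choice(L, size=n_variants, replace=False)) + 1
    cont = list(endo)
    for p in var_pos:
        cont[p - 1] = {"A": "T", "C": "G", "G": "C", "T": "A"}[cont[p - 1]]
    cont = "".join(cont)
    pile = simdata.simulate_mt_pileup(
        endo, cont, c_true, float(mt_cfg.get("coverage", 500)),
        float(mt_cfg.get("base_error", 1e-3)), rng,
    )
    est = estimate_contamination(pile, var_pos, sample="mt_demo")
    io.write_fasta(out / "mt_demo.fasta", {"endogenous": endo, "contaminant": cont})
    return {
        "true_contamination": c_true,
        "c_hat": est.c_hat,
        "ci": [est.ci_low, est.ci_high],
    }
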