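"""End-to-end depletion-analysis pipeline driver with a reproducible manifest.

Runs, in order: simulate (or load) -> balance -> expected/O-E -> saddle ->
APA pileups -> insulation -> loop statistics -> responsive-loop
classification -> permutation tests.  Every stage writes its artifact and the
manifest records parameters, seeds, stage status and a checksum for every
output file; a rerun with the same configuration is bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import simulate as sim
from .compartments import compartment_track, orient_eigenvector, saddle
from .contacts import expected_by_distance, filter_min_distance, ice_balance
from .genome import SignalTrack, write_track
from .loops import (
    classify_responsive_loops,
    gene_category_enrichment,
    length_rank_gsea,
    loop_strength_log2fc,
)
from .pileup import apa, insulation_score

logger = logging.getLogger("loopshift.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "min_pair_distance": 20000,
    "saddle_quantiles": 20,
    "saddle_top_frac": 0.2,
    "apa_flank_bins": 10,
    "insulation_window": 250000,
    "gsea_n_perm": 500,
    "gene_enrich_n_perm": 1000,
    "classify_top_n": None,  # default: number of planted responsive loops
    "simulation": {},        # overrides for SimulationConfig fields
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Run the depletion analysis end to end; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "loopshift",
        "config": config,
        "stages": {},
        "files": {},
    }
    t0 = time.time()

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, "t": round(time.time() - t0, 2), **extra}
        logger.info("stage %s: %s", stage, status)

    def emit(name, path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def save_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    sim_kwargs = dict(config.get("simulation") or {})
    sim_kwargs.setdefault("seed", config["seed"])
    scfg = sim.SimulationConfig(**sim_kwargs)
    manifest["simulation_config"] = asdict(scfg)

    try:
        # ------------------------------------------------------------ simulate
        exp = sim.simulate_perturbation_experiment(scfg)
        paths = sim.write_perturbation_dataset(exp, out / "inputs")
        for name, path in paths.items():
            emit(f"inputs/{name}", path)
        record("simulate", "ok", n_loops=len(exp.loops))

        # ------------------------------------------------------------- balance
        balanced = {}
        for cond, mats in (("untreated", exp.matrices_before), ("treated", exp.matrices_after)):
            balanced[cond] = {
                c: ice_balance(filter_min_distance(m, config["min_pair_distance"]))
                for c, m in mats.items()
            }
        record("balance", "ok")

        # ------------------------------------------------------- expected / OE
        expected = {
            cond: {c: expected_by_distance(m) for c, m in mats.items()}
            for cond, mats in balanced.items()
        }
        for cond in expected:
            frames = [p.to_frame() for p in expected[cond].values()]
            path = out / f"expected_{cond}.tsv"
            import pandas as pd

            pd.concat(frames).to_csv(path, sep="\t", index=False)
            emit(path.name, path)
        record("expected", "ok")

        # -------------------------------------------------------------- saddle
        saddle_out = {}
        for cond in balanced:
            e1 = compartment_track(balanced[cond], expected[cond])
            active = SignalTrack(
                scfg.bin_size,
                {c: (exp.truth.compartment_labels[c] > 0).astype(float) for c in e1.values},
                normalization="active_reference",
            )
            e1 = orient_eigenvector(e1, active)
            sres = saddle(
                balanced[cond], e1, expected[cond],
                n_quantiles=config["saddle_quantiles"], top_frac=config["saddle_top_frac"],
            )
            saddle_out[cond] = {
                "AA": sres.aa, "BB": sres.bb, "AB": sres.ab, "enrichment": sres.enrichment,
            }
            np.savetxt(out / f"saddle_{cond}.tsv", sres.matrix, delimiter="\t")
            emit(f"saddle_{cond}.tsv", out / f"saddle_{cond}.tsv")
        with open(out / "saddle_scores.json", "w") as fh:
            json.dump(saddle_out, fh, indent=1)
        emit("saddle_scores.json", out / "saddle_scores.json")
        record("saddle", "ok", **{c: round(v["enrichment"], 4) for c, v in saddle_out.items()})

        # ----------------------------------------------------------------- apa
        apa_out = {}
        for cond in balanced:
            res = apa(balanced[cond], exp.loops, expected[cond], flank_bins=config["apa_flank_bins"])
            apa_out[cond] = res.enrichment
            np.savetxt(out / f"apa_{cond}.tsv", res.matrix, delimiter="\t")
            emit(f"apa_{cond}.tsv", out / f"apa_{cond}.tsv")
        record("apa", "ok", **{c: round(v, 4) for c, v in apa_out.items()})

        # ---------------------------------------------------------- insulation
        for cond in balanced:
            ins = insulation_score(balanced[cond], window=config["insulation_window"])
            write_track(ins.to_track(), out / f"insulation_{cond}.bedgraph", exp.genome)
            emit(f"insulation_{cond}.bedgraph", out / f"insulation_{cond}.bedgraph")
        record("insulation", "ok")

        # ------------------------------------------------------ loop statistics
        ls = loop_strength_log2fc(
            balanced["untreated"], balanced["treated"], exp.loops,
            expected["untreated"], expected["treated"],
        )
        ls.to_csv(out / "loop_strength.tsv", sep="\t", index=False)
        emit("loop_strength.tsv", out / "loop_strength.tsv")
        record("loop_stats", "ok")

        # ------------------------------------------------------ classification
        top_n = config["classify_top_n"] or len(exp.truth.responsive_loops)
        cls = classify_responsive_loops(
            exp.loops, exp.tf_peaks, exp.down_cohesin_peaks, exp.atac_peaks,
            exp.tf_track, exp.cohesin_lfc_per_atac, top_n=top_n,
        )
        with open(out / "responsive_loops.json", "w") as fh:
            json.dump(
                {
                    "responsive": [int(i) for i in cls.responsive],
                    "less_responsive": [int(i) for i in cls.less_responsive],
                },
                fh, indent=1,
            )
        emit("responsive_loops.json", out / "responsive_loops.json")
        record("classify", "ok", n_responsive=len(cls.responsive))

        # ---------------------------------------------------- permutation tests
        gained = np.zeros(len(exp.loops), dtype=bool)
        gained[cls.responsive] = True
        perm_out = {}
        if 0 < gained.sum() < len(gained):
            gres, _ = length_rank_gsea(
                exp.loops, gained, n_perm=config["gsea_n_perm"], seed=config["seed"]
            )
            perm_out["length_gsea"] = {
                "es": gres.observed, "p": gres.p_value, "n_perm": gres.n_perm,
            }
        resp_set = exp.loops.subset(gained)
        genes_tss = np.array([g.tss for g in exp.genes])
        genes_chrom = np.array([g.chrom for g in exp.genes])
        enr = gene_category_enrichment(
            resp_set, genes_tss, genes_chrom, exp.gene_categories, exp.genome,
            n_perm=config["gene_enrich_n_perm"], seed=config["seed"],
        )
        perm_out["gene_category"] = {
            cat: {"ratio": r, "p": (t.p_value if t else None)} for cat, (r, t) in enr.items()
        }
        with open(out / "permutation_tests.json", "w") as fh:
            json.dump(perm_out, fh, indent=1)
        emit("permutation_tests.json", out / "permutation_tests.json")
        record("permtest", "ok")
    except Exception as exc:  # fail fast but keep partial results + manifest
        stage = "unknown"
        for name in ("simulate", "balance", "expected", "saddle", "apa",
                     "insulation", "loop_stats", "classify", "permtest"):
            if name not in manifest["stages"]:
                stage = name
                break
        record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
        save_manifest()
        raise

    manifest["status"] = "ok"
    save_manifest()
    return manifest
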