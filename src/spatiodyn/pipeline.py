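"""End-to-end orchestration: synthetic generation -> QPP/cPCA per cohort ->
integrity vs reference -> group statistics -> results bundle on disk.

Configuration is a plain mapping (typically loaded from YAML). Every run is
fully reproducible from (config, seed); the results directory carries a
manifest with a checksum and provenance sidecar for each artifact.
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

from . import io as sio
from .atlas import AtlasMap, default_atlas
from .cpca import cpca, reconstruct_pattern
from .integrity import (domain_block_values, engagement_scores,
                        integrity_delta, phase_locked_template, template_corr)
from .preprocess import preprocess
from .qpp import QPPConfig, detect_qpp
from .stats import compare_cohorts
from .synthetic import generate_background, plant_qpp
from .experiments import make_domain_template

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "tr_seconds": 3.0,
    "atlas": "default",
    "alpha": 0.05,
    "bonferroni_scope": "per_domain",
    "preprocess": ["bandpassed", "gsr", "zscored"],
    "qpp": {},              # QPPConfig overrides
    "cpca": {"n_components": 1},
    "cohorts": [],
}


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(yaml.safe_load(Path(path).read_text()) or {})
    return cfg


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _get_atlas(config: dict) -> AtlasMap:
    spec = config.get("atlas", "default")
    return default_atlas() if spec == "default" else sio.load_atlas(spec)


def _cohort_series(cohort: dict, config: dict, atlas: AtlasMap, rng_seed: int,
                   template: np.ndarray | None):
    """Load a cohort from disk or synthesise it per the config."""
    tr = config["tr_seconds"]
    if "path" in cohort:
        return sio.load_timeseries(cohort["path"], cohort.get("tr_seconds", tr))
    syn = cohort.get("synthetic")
    if syn is None:
        raise ValueError(f"cohort {cohort.get('label')!r} has neither a path "
                         "nor a synthetic block")
    rng_seed = int(syn.get("seed", rng_seed))  # override: identical cohorts
    n_icn = atlas.n_icn
    bg = generate_background(
        n_icn, syn.get("n_timepoints", 800), tr,
        global_signal_weight=syn.get("global_signal_weight", 0.0),
        noise_sd=syn.get("noise_sd", 1.0), seed=rng_seed)
    if template is None or not syn.get("plant", True):
        return bg
    amp = np.full(n_icn, float(syn.get("amplitude", 1.0)))
    att = syn.get("attenuate")
    if att:
        ids = sorted(atlas.icn_to_subdomain)
        for icn in atlas.icns_in_domain(att["domain"]):
            amp[ids.index(icn)] *= float(att.get("factor", 0.5))
    planted, _ = plant_qpp(bg, template, syn.get("mean_interval_tr", 26),
                           syn.get("jitter_tr", 3), amp, seed=rng_seed + 1)
    return planted


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis and write a results bundle.

    Returns a summary dict with the comparison result, per-cohort outputs
    and the output-file manifest. Exactly one cohort must carry the
    ``reference`` role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_CONFIG, **config}
    atlas = _get_atlas(cfg)
    cohorts = cfg["cohorts"]
    refs = [c["label"] for c in cohorts if c.get("role") == "reference"]
    if len(refs) != 1:
        raise ValueError(f"exactly one reference cohort required, got {refs}")
    reference = refs[0]

    ss = np.random.SeedSequence(int(cfg["seed"]))
    sub = ss.spawn(len(cohorts) + 2)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    tmpl_seed, qpp_seed = seeds[-2], seeds[-1]

    any_synthetic = any("synthetic" in c for c in cohorts)
    shared_template = (make_domain_template(atlas, seed=tmpl_seed)
                       if any_synthetic else None)

    qcfg = QPPConfig(seed=qpp_seed, **cfg.get("qpp", {}))
    stage_results: dict[str, dict] = {}
    t0 = time.time()
    for cohort, seed in zip(cohorts, seeds):
        label = cohort["label"]
        logger.info("cohort %s: generate/load + preprocess", label)
        try:
            ts = _cohort_series(cohort, cfg, atlas, seed, shared_template)
            steps = tuple(s for s in cfg["preprocess"] if s not in ts.flags)
            ts = preprocess(ts, steps=steps)
            logger.info("cohort %s: QPP detection", label)
            q = detect_qpp(ts, qcfg)
            logger.info("cohort %s: cPCA", label)
            cp = cpca(ts, n_components=cfg["cpca"].get("n_components", 1))
        except Exception as exc:
            (out / "FAILED").write_text(f"stage failed for cohort {label}: {exc}\n")
            raise RuntimeError(f"pipeline failed at cohort {label!r}: {exc}") from exc
        W = q.window_frames
        stage_results[label] = {
            "series": ts, "qpp": q, "cpca": cp,
            "cpca_pattern": reconstruct_pattern(cp.loadings[:, 0], W),
            "engagement": engagement_scores(cp, atlas),
        }
        cdir = out / f"cohort_{label}"
        sio.save_qpp(q, cdir)
        sio.save_template(stage_results[label]["cpca_pattern"],
                          cdir / "cpca_pattern.tsv", ts.icn_ids)
        pd.DataFrame({"icn_id": list(ts.icn_ids),
                      "amplitude": cp.amplitude_map,
                      "phase_rad": cp.phase_map}).to_csv(
            cdir / "cpca_maps.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": cp.eigenvalues}).to_csv(
            cdir / "cpca_eigenvalues.tsv", sep="\t", index=False)

    # integrity vs reference, for both QPP and cPCA template routes.
    # Group statistics compare each cohort's *self*-correlation values
    # (invariant to the template's arbitrary phase); the cross matrices and
    # deltas use the phase-locked comparison template.
    summary: dict = {"reference": reference, "cohorts": list(stage_results)}
    values_by_cohort = {"qpp": {}, "cpca": {}}
    ref = stage_results[reference]
    for source in ("qpp", "cpca"):
        ref_pat = (ref["qpp"].pattern if source == "qpp"
                   else ref["cpca_pattern"])
        c_self = template_corr(ref_pat, ref_pat, reference, reference, source)
        for label, res in stage_results.items():
            if source == "qpp":
                pat = phase_locked_template(res["series"], res["qpp"], ref_pat)
            else:
                from .integrity import align_templates
                pat = align_templates(ref_pat, res["cpca_pattern"]).pattern
            c_own = template_corr(pat, pat, label, label, source)
            c_cross = template_corr(ref_pat, pat, reference, label, source)
            delta = integrity_delta(c_self, c_cross)
            values_by_cohort[source][label] = {
                d: domain_block_values(c_own, atlas, d)
                for d in atlas.domains}
            base = out / f"integrity_{source}_{reference}_vs_{label}"
            np.savetxt(f"{base}_C.tsv", c_cross.C, delimiter="\t")
            np.savetxt(f"{base}_delta.tsv", delta.delta, delimiter="\t")

    comparison = compare_cohorts(values_by_cohort["qpp"], alpha=cfg["alpha"],
                                 bonferroni_scope=cfg["bonferroni_scope"])
    comparison_cpca = compare_cohorts(values_by_cohort["cpca"],
                                      alpha=cfg["alpha"],
                                      bonferroni_scope=cfg["bonferroni_scope"])
    for name, res in (("qpp", comparison), ("cpca", comparison_cpca)):
        res.domain_table.to_csv(out / f"stats_{name}_domains.tsv", sep="\t",
                                index=False)
        res.pairwise_table.to_csv(out / f"stats_{name}_pairwise.tsv", sep="\t",
                                  index=False)
        res.pair_mask.to_csv(out / f"stats_{name}_mask.tsv", sep="\t")

    engagement_rows = [
        {"cohort": label, "domain": d, "source": "cpca_loading", "value": v}
        for label, res in stage_results.items()
        for d, v in res["engagement"].scores.items()]
    pd.DataFrame(engagement_rows).to_csv(out / "engagement.tsv", sep="\t",
                                         index=False)

    provenance = {"config_hash": _config_hash(cfg), "seed": cfg["seed"],
                  "elapsed_seconds": round(time.time() - t0, 2)}
    files = sorted(p for p in out.rglob("*.tsv"))
    manifest = {str(p.relative_to(out)): sio.sha256_of(p) for p in files}
    (out / "manifest.json").write_text(
        json.dumps({"provenance": provenance, "files": manifest}, indent=2)
        + "\n")
    summary.update(comparison=comparison, comparison_cpca=comparison_cpca,
                   stage_results=stage_results, manifest=manifest,
                   provenance=provenance)
    return summary
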