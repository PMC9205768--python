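"""End-to-end orchestration: config validation, stage wiring, manifest, report.

A single YAML config drives the whole analysis. Every published threshold is
a named, defaulted field, so the zero-override run reproduces the study's
settings. Stages write serialized outputs (TSV/JSON) into the run directory,
a reproducibility manifest records config hash, seeds and input checksums,
and a markdown report collects the headline numbers plus the 2-D CCF figure
and posterior summary.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock, clustering, consensus, synthetic, timing

#: full default config; unknown keys anywhere below are rejected
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scenario": "synthetic",  # 'synthetic' | 'counts_only' | 'vcf'
    "synthetic": {
        "rate_per_year": 2.5,
        "t_mrca_true": 0.6,
        "sampling_age_a": 40.0,
        "sampling_age_b": 40.0,
        "ncptg_fraction": 1.0,
        "depth_mean": 40.0,
        "purity_a": 0.95,
        "purity_b": 0.95,
        "caller_sensitivity": [1.0, 1.0, 1.0],
        "caller_false_calls": [0, 0, 0],
    },
    "inputs": {
        "twin_a_vcfs": [],
        "twin_b_vcfs": [],
        "counts": None,  # {'s':..,'n_a':..,'n_b':..,'context_class':..}
    },
    "filters": {
        "germline_vaf_max": 0.05,
        "tumor_vaf_min": 0.1,
        "min_depth": 20,
        "cluster_min_fraction": 0.01,
        "sv_slop_bp": 200,
        "pigeonhole_ccf": 0.5,
    },
    "clustering": {
        "dims": 2,
        "concentration": 1.0,
        "iters": 1000,
        "burn_in": 200,
    },
    "timing": {
        "context_class": "ncptg",
        "rate_prior_mean": None,  # default per context class
        "rate_upper_bound": None,
        "sampling_age_a": None,   # default: case-study ages
        "sampling_age_b": None,
        "post_mrca_interval_mode": "latent_endpoint",
        "chains": 4,
        "iters": 6000,
        "warmup": 1500,
    },
    "report": {"make_plots": True},
}


class ConfigError(ValueError):
    """Config validation failure carrying the full list of violations."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def validate_config(config: str | Path | dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys.

    Accepts a YAML path, a dict, or None (pure defaults). Returns the fully
    normalized config; raises ConfigError listing every violation.
    """
    if config is None:
        user: dict = {}
    elif isinstance(config, dict):
        user = config
    else:
        user = yaml.safe_load(Path(config).read_text()) or {}

    errors: list[str] = []
    merged = _merge("", DEFAULT_CONFIG, user, errors)
    f = merged["filters"]
    if f["min_depth"] < 0:
        errors.append("filters.min_depth must be >= 0")
    if not 0 <= f["germline_vaf_max"] <= 1 or not 0 <= f["tumor_vaf_min"] <= 1:
        errors.append("VAF thresholds must lie in [0, 1]")
    if f["sv_slop_bp"] < 0:
        errors.append("filters.sv_slop_bp must be >= 0")
    if not 0 <= f["cluster_min_fraction"] < 1:
        errors.append("filters.cluster_min_fraction must lie in [0, 1)")
    if merged["scenario"] not in ("synthetic", "counts_only", "vcf"):
        errors.append(f"unknown scenario {merged['scenario']!r}")
    if errors:
        raise ConfigError(errors)
    return merged


def _merge(prefix: str, default: dict, user: dict, errors: list[str]) -> dict:
    out = {}
    for key, dval in default.items():
        if isinstance(dval, dict) and key in user and user[key] is not None:
            if not isinstance(user[key], dict):
                errors.append(f"{prefix}{key} must be a mapping")
                out[key] = dval
            else:
                out[key] = _merge(f"{prefix}{key}.", dval, user[key], errors)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval if not isinstance(dval, dict) else dict(dval)
    for key in user:
        if key not in default:
            errors.append(f"unknown config key: {prefix}{key}")
    return out


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def build_manifest(config: dict, input_paths: list[Path], stage_seeds: dict) -> dict:
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_hash": _sha256(payload),
        "seeds": stage_seeds,
        "inputs": {str(p): _sha256(Path(p).read_bytes()) for p in input_paths},
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: str | Path | dict | None, out_dir: str | Path) -> Path:
    """Run consensus -> clustering -> lineage -> clock counts -> timing.

    Returns the report directory. Any stage failure moves partial outputs to
    ``<out_dir>/failed/`` and re-raises the stage's diagnostic.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_stages(cfg, out)
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in [p for p in out.iterdir() if p.name != "failed"]:
            shutil.move(str(item), str(failed / item.name))
        raise


def _run_stages(cfg: dict, out: Path) -> Path:
    seed = int(cfg["seed"])
    manifest_seeds = {"root": seed}
    results: dict = {}

    if cfg["scenario"] == "counts_only":
        counts_cfg = cfg["inputs"]["counts"]
        if not counts_cfg:
            raise ConfigError(["counts_only scenario requires inputs.counts"])
        counts = clock.LineageCounts(
            int(counts_cfg["s"]), int(counts_cfg["n_a"]), int(counts_cfg["n_b"]),
            counts_cfg.get("context_class", cfg["timing"]["context_class"]))
    else:
        counts, results = _stages_from_variants(cfg, out, seed, manifest_seeds)

    (out / "lineage_counts.json").write_text(json.dumps(counts.as_dict(), indent=2))

    tcfg = _timing_config(cfg, counts, seed)
    enough_draws = tcfg.chains * (tcfg.iters - tcfg.warmup) >= 4000
    fit = timing.fit_mcmc(tcfg, compute_log_ml=enough_draws)
    summary = fit.summary.reset_index().to_dict(orient="records")
    timing_out = {
        "posterior": summary,
        "log_marginal_likelihood": fit.log_marginal_likelihood,
        "log_ml_se": fit.log_ml_se,
        "counts": counts.as_dict(),
        "t_mrca_prior_upper": tcfg.t_upper,
    }
    (out / "timing_summary.json").write_text(
        json.dumps(timing_out, indent=2, default=float))
    fit_df = pd.DataFrame({k: v.reshape(-1) for k, v in fit.draws.items()})
    fit_df.to_csv(out / "posterior_draws.csv", index=False)

    manifest = build_manifest(cfg, [], manifest_seeds)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    _write_report(cfg, out, counts, fit, results)
    return out


def _stages_from_variants(cfg: dict, out: Path, seed: int, manifest_seeds: dict):
    """Synthetic (or VCF) variants -> partition -> clustering -> counts."""
    f = cfg["filters"]
    if cfg["scenario"] == "synthetic":
        s = cfg["synthetic"]
        params = synthetic.SimulationParams(
            rate_per_year=s["rate_per_year"], t_mrca_true=s["t_mrca_true"],
            sampling_age_a=s["sampling_age_a"], sampling_age_b=s["sampling_age_b"],
            ncptg_fraction=s["ncptg_fraction"], depth_mean=s["depth_mean"],
            purity_a=s["purity_a"], purity_b=s["purity_b"],
            caller_sensitivity=tuple(s["caller_sensitivity"]),
            caller_false_calls=tuple(s["caller_false_calls"]), seed=seed)
        manifest_seeds["synthetic"] = seed
        truth = synthetic.simulate_twin_history(params)
        observed = synthetic.simulate_observations(truth)
        vcf_dir = out / "vcf"
        sets = {}
        for twin in "ab":
            paths = synthetic.emit_caller_callsets(
                observed, vcf_dir, twin=twin,
                caller_sensitivity=params.caller_sensitivity,
                caller_false_calls=params.caller_false_calls,
                seed=seed + (1 if twin == "a" else 2))
            calls = [consensus.read_caller_vcf(paths[c], consensus.CALLER_DIALECTS[c])
                     for c in ("mutect2", "strelka2", "octopus")]
            sets[twin] = consensus.intersect_callers(*calls)
        partition = consensus.classify_shared_unique(sets["a"], sets["b"])
        purity = (s["purity_a"], s["purity_b"])
        observed_table = observed
    else:
        raise NotImplementedError(
            "direct VCF inputs: use the library API (read_caller_vcf etc.)")

    part_df = partition.to_frame()
    part_df.to_csv(out / "partition.tsv", sep="\t", index=False)

    # join with the simulator's per-twin observations for 2-D clustering
    merged = part_df.merge(
        observed_table[["chrom", "pos", "ref", "alt", "context",
                        "alt_a", "depth_a", "alt_b", "depth_b", "cn_total"]],
        on=["chrom", "pos", "ref", "alt"], how="inner")
    ccfg = cfg["clustering"]
    records = clustering.build_ccf_records(merged, purity)
    solution = clustering.cluster_ccf(
        records, purity, n_dims=ccfg["dims"], concentration=ccfg["concentration"],
        iters=ccfg["iters"], burn_in=ccfg["burn_in"], seed=seed + 11)
    solution = clustering.prune_clusters(
        solution, records, purity, min_fraction=f["cluster_min_fraction"])
    labels = clustering.assign_lineages_pigeonhole(
        solution, threshold=f["pigeonhole_ccf"])
    labels.to_csv(out / "clusters.tsv", sep="\t", index=False)
    merged["cluster"] = solution.assignments
    merged.to_csv(out / "assignments.tsv", sep="\t", index=False)

    context = cfg["timing"]["context_class"]
    counts = clock.assemble_lineage_counts(
        merged, labels[["cluster", "label"]], context_filter=context,
        min_depth=f["min_depth"])
    return counts, {"partition": part_df, "labels": labels, "merged": merged,
                    "solution": solution}


def _timing_config(cfg: dict, counts: clock.LineageCounts, seed: int
                   ) -> timing.TimingConfig:
    t = cfg["timing"]
    mu = t["rate_prior_mean"]
    if mu is None:
        mu = (timing.RATE_PRIOR_MEAN_NCPTG if counts.context_class == "ncptg"
              else timing.RATE_PRIOR_MEAN_ALL_CLONAL)
    kwargs = dict(
        counts=counts, rate_prior_mean=mu, rate_upper_bound=t["rate_upper_bound"],
        post_mrca_interval_mode=t["post_mrca_interval_mode"],
        chains=int(t["chains"]), iters=int(t["iters"]), warmup=int(t["warmup"]),
        seed=seed + 23)
    if t["sampling_age_a"] is not None:
        kwargs["sampling_age_a"] = float(t["sampling_age_a"])
    if t["sampling_age_b"] is not None:
        kwargs["sampling_age_b"] = float(t["sampling_age_b"])
    if cfg["scenario"] == "synthetic":
        s = cfg["synthetic"]
        kwargs.setdefault("sampling_age_a", s["sampling_age_a"])
        kwargs.setdefault("sampling_age_b", s["sampling_age_b"])
        kwargs["t_mrca_prior_upper"] = min(
            kwargs["sampling_age_a"], kwargs["sampling_age_b"]) + synthetic.GESTATION_YEARS - 1e-6
    return timing.TimingConfig(**kwargs)


def _write_report(cfg: dict, out: Path, counts, fit, results: dict) -> None:
    lines = [
        "# twinclock run report", "",
        f"- scenario: {cfg['scenario']}",
        f"- lineage counts ({counts.context_class}): "
        f"s={counts.s_shared}, n_A={counts.n_unique_a}, n_B={counts.n_unique_b}",
        "",
        "## Posterior timing summary", "",
        fit.summary.to_markdown(), "",
        f"log marginal likelihood: {fit.log_marginal_likelihood:.3f} "
        f"(se {fit.log_ml_se:.3f})" if fit.log_marginal_likelihood is not None else "",
    ]
    if cfg["report"]["make_plots"]:
        try:
            _plot(out, fit, results)
            lines += ["", "![CCF clusters](ccf_clusters.png)",
                      "![t_MRCA posterior](t_mrca_posterior.png)"]
        except Exception as exc:  # plotting must never sink a run
            lines += ["", f"(plots unavailable: {exc})"]
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _plot(out: Path, fit, results: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "solution" in results:
        sol = results["solution"]
        merged = results["merged"]
        fig, ax = plt.subplots(figsize=(5, 5))
        if sol.n_dims == 2:
            from .clustering import build_ccf_records  # noqa: F401  (doc pointer)
            ccf_a = merged["alt_a"] / merged["depth_a"].clip(lower=1) * 2
            ccf_b = merged["alt_b"] / merged["depth_b"].clip(lower=1) * 2
            ax.scatter(ccf_a, ccf_b, s=8, c=sol.assignments, cmap="tab10", alpha=0.6)
            ax.scatter(sol.locations[:, 0], sol.locations[:, 1], marker="x",
                       c="black", s=80)
            ax.set_xlabel("CCF twin A")
            ax.set_ylabel("CCF twin B")
        fig.savefig(out / "ccf_clusters.png", dpi=110)
        plt.close(fig)

    if "t_mrca" in fit.draws:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.hist(fit.draws["t_mrca"].reshape(-1), bins=80, density=True)
        ax.set_xlabel("t_MRCA (years from fertilization)")
        ax.set_ylabel("posterior density")
        fig.tight_layout()
        fig.savefig(out / "t_mrca_posterior.png", dpi=110)
        plt.close(fig)
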