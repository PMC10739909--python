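"""End-to-end orchestration: configuration, staged runs, behavior summary.

A :class:`RunConfig` fully determines a run (simulate -> preprocess ->
spectral -> cluster -> pte -> inference); every stochastic stage draws
from seeds recorded in the config, outputs land as tab-separated tables
plus one HDF5 container, and a JSON run log (config hash, seeds, package
version) makes any number in the output reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .containers import HC_REGIONS, NC_PTE_REGIONS
from .cluster import cluster_correct, paired_tmap, permutation_null
from .preprocess import (detect_artifacts, downsample, epoch_trials,
                         laplacian_reference, notch_filter)
from .pte import PTEParams, extract_phase, pte_pair
from .simulate import SimConfig, simulate_session
from .spectral import WaveletConfig, average_and_offset, baseline_zscore, \
    morlet_power
from .stats import fdr_correct, paired_permutation_test

logger = logging.getLogger("thetaflow")

ALL_STAGES = ("simulate", "preprocess", "spectral", "cluster", "pte",
              "inference")


class PipelineError(RuntimeError):
    """A stage failed or a stage dependency is missing."""


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    stages: tuple = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    n_nc: int = 2
    n_hc: int = 2
    target_fs: float = 500.0
    line_freq: float = 60.0
    n_harmonics: int = 3
    k_sd: float = 4.0
    artifact_pad_s: float = 1.0
    task_phase: str = "retrieval"
    epoch_window: tuple = (-1.0, 1.0)
    baseline_window: tuple = (-0.5, 0.0)
    baseline_mode: str = "condition_baseline"
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    contrast: tuple = ("lure+", "lure-")
    band: tuple = (4.0, 5.0)
    cluster_forming_p: float = 0.05
    cluster_connectivity: int = 8
    pte: PTEParams = field(default_factory=PTEParams)
    n_perm: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["sim"] = SimConfig(**raw["sim"])
        raw["wavelet"] = WaveletConfig(**raw["wavelet"])
        pte_raw = raw["pte"]
        for key in ("window",):
            if pte_raw.get(key) is not None:
                pte_raw[key] = tuple(pte_raw[key])
        raw["pte"] = PTEParams(**pte_raw)
        for key in ("stages", "epoch_window", "baseline_window",
                    "contrast", "band"):
            raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def summarize_behavior(events: pd.DataFrame) -> dict:
    """Per-category and overall retrieval accuracy percentages.

    Categories are the stimulus families (repeat, lure, new) derived from
    the condition labels; a category with no trials is absent from the
    output, not reported as 0%.
    """
    retrieval = events.loc[events["phase"] == "retrieval"]
    if retrieval.empty:
        raise ValueError("no retrieval events to summarize")
    correct = retrieval["correct"].to_numpy(dtype=float)
    out = {"overall": 100.0 * correct.mean(),
           "n_trials": int(len(retrieval))}
    categories = retrieval["condition"].str.rstrip("+-")
    for cat, grp in retrieval.groupby(categories, sort=False):
        out[str(cat)] = 100.0 * grp["correct"].to_numpy(dtype=float).mean()
    return out


def _require(results: dict, key: str, needed_by: str):
    if key not in results:
        raise PipelineError(
            f"stage {needed_by!r} needs missing artifact {key!r} "
            "(is its producing stage toggled on?)")
    return results[key]


def run_pipeline(config: RunConfig, out_dir=None,
                 dataset=None) -> dict:
    """Execute the configured stages and return the result bundle.

    ``dataset`` may supply a pre-built :class:`SyntheticDataset` (or any
    object with ``recording``/``events`` attributes) instead of the
    simulate stage.  With ``out_dir``, tidy TSV tables, an HDF5
    container, and a JSON run log are written.
    """
    results: dict = {"config": config}
    stages = tuple(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")

    if dataset is not None:
        results["dataset"] = dataset
    elif "simulate" in stages:
        try:
            results["dataset"] = simulate_session(
                config.sim, n_nc=config.n_nc, n_hc=config.n_hc)
        except Exception as err:
            raise PipelineError(f"stage 'simulate' failed: {err}") from err

    if "preprocess" in stages:
        ds = _require(results, "dataset", "preprocess")
        try:
            raw = downsample(ds.recording, config.target_fs)
            raw = notch_filter(raw, config.line_freq, config.n_harmonics)
            raw = laplacian_reference(raw)
            mask = detect_artifacts(raw, config.k_sd, config.artifact_pad_s)
            events = ds.events.loc[
                ds.events["phase"] == config.task_phase]
            epochs = epoch_trials(raw, events, mask, alignment="onset",
                                  window=tuple(config.epoch_window))
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'preprocess' failed: {err}") from err
        results["raw"] = raw
        results["mask"] = mask
        results["epochs"] = epochs

    if "spectral" in stages:
        epochs = _require(results, "epochs", "spectral")
        try:
            power = morlet_power(epochs, config.wavelet)
            zmaps = baseline_zscore(power,
                                    tuple(config.baseline_window),
                                    config.baseline_mode)
            averages = average_and_offset(zmaps)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'spectral' failed: {err}") from err
        results["power"] = power
        results["zmaps"] = zmaps
        results["averages"] = averages

    if "cluster" in stages:
        zmaps = _require(results, "zmaps", "cluster")
        averages = _require(results, "averages", "cluster")
        cond_a, cond_b = config.contrast
        try:
            a = averages[cond_a]
            b = averages[cond_b]
            t_map = paired_tmap(a, b)
            null_t = permutation_null(a, b, n_perm=config.n_perm,
                                      seed=config.seed + 1)
            clusters = cluster_correct(t_map, null_t,
                                       config.cluster_forming_p,
                                       config.cluster_connectivity)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'cluster' failed: {err}") from err
        results["clusters"] = clusters

    if "pte" in stages:
        epochs = _require(results, "epochs", "pte")
        try:
            chans = epochs.channels
            nc = chans.loc[chans["region"].isin(NC_PTE_REGIONS), "label"]
            hc = chans.loc[chans["region"].isin(HC_REGIONS), "label"]
            rows = []
            phase_cache: dict = {}

            def phases_for(label, sub):
                key = (label, id(sub))
                if key not in phase_cache:
                    phase_cache[key] = extract_phase(sub, label,
                                                     tuple(config.band))
                return phase_cache[key]

            for cond in dict.fromkeys(epochs.conditions):
                sub = epochs.select(cond)
                if sub.n_trials < 2:
                    continue
                for nc_label in nc:
                    for hc_label in hc:
                        px = phases_for(nc_label, sub)
                        py = phases_for(hc_label, sub)
                        res = pte_pair(px, py, config.pte)
                        rows.append({
                            "pair_id": f"{nc_label}->{hc_label}",
                            "nc_channel": nc_label, "hc_channel": hc_label,
                            "condition": cond,
                            "phase": config.task_phase,
                            "pte_nchc_bits": res["pte_xy_bits"],
                            "pte_hcnc_bits": res["pte_yx_bits"],
                            "pte_norm": res["pte_norm"],
                        })
            pte_table = pd.DataFrame(rows)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'pte' failed: {err}") from err
        results["pte_table"] = pte_table

    if "inference" in stages:
        pte_table = _require(results, "pte_table", "inference")
        ds = _require(results, "dataset", "inference")
        cond_a, cond_b = config.contrast
        try:
            wide = pte_table.pivot(index="pair_id", columns="condition",
                                   values="pte_norm")
            test = paired_permutation_test(
                wide[cond_a].to_numpy(), wide[cond_b].to_numpy(),
                n_perm=config.n_perm, seed=config.seed + 2,
                unit="channel pairs")
            flags, threshold = fdr_correct([test.p_value])
            stats_table = pd.DataFrame([{
                "contrast": f"{cond_a} vs {cond_b}",
                "unit": test.unit, "n": test.n_obs,
                "effect": test.observed, "p": test.p_value,
                "p_fdr_pass": bool(flags[0]), "seed": config.seed + 2,
            }])
            behavior = summarize_behavior(ds.events)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'inference' failed: {err}") from err
        results["stats_table"] = stats_table
        results["behavior"] = behavior

    if out_dir is not None:
        _write_bundle(results, Path(out_dir))
    return results


def _write_bundle(results: dict, out_dir: Path) -> None:
    from .io import write_container

    out_dir.mkdir(parents=True, exist_ok=True)
    config: RunConfig = results["config"]
    if "pte_table" in results:
        results["pte_table"].to_csv(out_dir / "pte_pairs.tsv", sep="\t",
                                    index=False)
    if "stats_table" in results:
        results["stats_table"].to_csv(out_dir / "contrasts.tsv", sep="\t",
                                      index=False)
    if "behavior" in results:
        pd.DataFrame([results["behavior"]]).to_csv(
            out_dir / "behavior.tsv", sep="\t", index=False)
    arrays = {}
    if "zmaps" in results:
        arrays["zmaps/z"] = results["zmaps"].z
        arrays["zmaps/freqs"] = results["zmaps"].freqs
        arrays["zmaps/times"] = results["zmaps"].times
    if "clusters" in results:
        cl = results["clusters"]
        arrays["cluster/t_map"] = cl.t_map
        arrays["cluster/p_map"] = cl.p_map
        arrays["cluster/null_max_pos"] = cl.null_max_pos
        arrays["cluster/null_max_neg"] = cl.null_max_neg
        cl.to_frame(results["zmaps"].freqs if "zmaps" in results else None,
                    results["zmaps"].times if "zmaps" in results else None
                    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    if arrays:
        write_container(out_dir / "results.h5", arrays,
                        attrs={"config_hash": config.config_hash,
                               "seed": config.seed,
                               "version": _version})
    (out_dir / "run_log.json").write_text(json.dumps({
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "version": _version,
        "stages": list(results.keys()),
    }, indent=2))
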