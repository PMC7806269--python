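"""File formats, run configuration and pipeline orchestration.

All tabular artifacts are plain CSV (one row per trial / frame / dot),
configuration and results are JSON.  Angles are degrees, times seconds,
reliabilities deg^-2 throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from avlearn import behavior, fitting, sequences
from avlearn.observers import ObserverParams, simulate_observer
from avlearn.sequences import Dataset, NoiseSequence, Trial

logger = logging.getLogger("avlearn")


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a session as trials.csv + dots.csv + sequence.csv + meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "trial_idx": i,
            "onset_s": t.onset,
            "v_mean_deg": t.v_mean,
            "a_loc_deg": t.a_loc,
            "sigma_true_deg": t.sigma_true,
            "n_dots": t.n_dots,
        }
        for i, t in enumerate(dataset.trials)
    ]
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    dots = [
        {"trial_idx": i, "dot_idx": j, "x_deg": x, "y_deg": y}
        for i, t in enumerate(dataset.trials)
        for j, (x, y) in enumerate(zip(t.dots_x, t.dots_y))
    ]
    pd.DataFrame(dots).to_csv(out / "dots.csv", index=False)
    seq = dataset.sequence
    pd.DataFrame(
        {"frame_time_s": seq.frame_times, "sigma_deg": seq.sigma_v}
    ).to_csv(out / "sequence.csv", index=False)
    meta = dict(dataset.metadata)
    meta.update({"kind": seq.kind, "period_s": seq.period, "seed": dataset.seed})
    if seq.jump_spec:
        meta["jump_spec"] = [[t, d] for t, d in seq.jump_spec]
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_dataset(in_dir: str | Path) -> Dataset:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    seq_df = pd.read_csv(src / "sequence.csv")
    jump_spec = [tuple(j) for j in meta.get("jump_spec", [])] or None
    seq = NoiseSequence(
        seq_df["frame_time_s"].to_numpy(),
        seq_df["sigma_deg"].to_numpy(),
        meta["kind"],
        meta["period_s"],
        jump_spec,
    )
    trials_df = pd.read_csv(src / "trials.csv")
    dots_df = pd.read_csv(src / "dots.csv")
    grouped = dict(tuple(dots_df.groupby("trial_idx")))
    trials = []
    for _, row in trials_df.iterrows():
        g = grouped[row["trial_idx"]].sort_values("dot_idx")
        trials.append(
            Trial(
                row["onset_s"],
                row["v_mean_deg"],
                row["a_loc_deg"],
                row["sigma_true_deg"],
                g["x_deg"].to_numpy(),
                g["y_deg"].to_numpy(),
            )
        )
    return Dataset(trials, seq, int(meta.get("seed", 0)), meta)


def write_responses(
    responses: np.ndarray, out_path: str | Path, model: str = "", seed: int = 0
) -> Path:
    df = pd.DataFrame(
        {
            "trial_idx": np.arange(len(responses)),
            "response_deg": np.asarray(responses, dtype=float),
            "model": model,
            "seed": seed,
        }
    )
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    return Path(out_path)


def read_responses(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).sort_values("trial_idx")["response_deg"].to_numpy()


def write_filter_trace(estimates, trace, out_path: str | Path) -> Path:
    """Per-trial Bayesian-filter trace CSV: posterior moments of the
    log-reliability belief, causal posterior and location estimate."""
    df = pd.DataFrame(
        {
            "trial_idx": np.arange(len(estimates)),
            "post_mean_loglambda": [p.mean_log_lambda() for p in trace],
            "post_sd_loglambda": [np.sqrt(p.var_log_lambda()) for p in trace],
            "p_c1": [e.p_c1 for e in estimates],
            "s_hat": [e.s_hat for e in estimates],
        }
    )
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    return Path(out_path)


def write_mh_samples(fit, out_path: str | Path) -> Path:
    """Posterior samples CSV: one row per (chain, step) with the parameter
    values on their natural scales."""
    names = list(fit.samples)
    n_chains, n_kept = fit.samples[names[0]].shape
    rows = {
        "chain": np.repeat(np.arange(n_chains), n_kept),
        "step": np.tile(np.arange(n_kept), n_chains),
    }
    for name in names:
        rows[name] = fit.samples[name].reshape(-1)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return Path(out_path)


def params_to_json(params: ObserverParams) -> dict:
    return {k: v for k, v in asdict(params).items() if v is not None}


def params_from_json(data: dict) -> ObserverParams:
    return ObserverParams(**data)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; every stochastic stage is seeded."""

    kind: str = "sinusoid"
    duration: float = 3900.0
    n_dots: int = 20
    model: str = "bayesian"
    params: dict = field(
        default_factory=lambda: {"sigma_a": 6.0, "p_common": 0.7, "sigma_0": 12.0, "kappa": 15.0}
    )
    seed_session: int = 1
    seed_responses: int = 2
    seed_fit: int = 3
    fit: bool = False
    fit_chains: int = 4
    fit_steps: int = 100
    fit_thin: int = 4
    fit_n_samples: int = 200
    exact_moments: bool = False

    def validate(self) -> None:
        for name in ("seed_session", "seed_responses", "seed_fit"):
            if getattr(self, name) is None:
                raise ValueError(f"missing seed: {name}")
        if self.kind not in ("sinusoid", "rw1", "rw2", "jump"):
            raise ValueError(f"unknown kind: {self.kind!r}")
        if self.model not in fitting.MODELS:
            raise ValueError(f"unknown model: {self.model!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        cfg = cls(**json.loads(text))
        cfg.validate()
        return cfg

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """generate -> simulate -> analyze (-> fit), writing every artifact and
    a manifest with the config hash; refuses to resume into a directory
    produced by a different configuration."""
    config.validate()
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_digest") != config.digest:
            raise ValueError("output directory holds a run with a different config")
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    t0 = time.perf_counter()
    logger.info("stage=generate seed=%d", config.seed_session)
    dataset = sequences.make_session(
        config.kind, config.duration, config.n_dots, config.seed_session,
        config.exact_moments,
    )
    write_dataset(dataset, out / "data")
    logger.info("stage=simulate seed=%d t=%.2fs", config.seed_responses,
                time.perf_counter() - t0)
    params = params_from_json(config.params)
    responses = simulate_observer(dataset, params, config.model, config.seed_responses)
    write_responses(responses, out / "responses.csv", config.model, config.seed_responses)

    logger.info("stage=analyze t=%.2fs", time.perf_counter() - t0)
    profile = behavior.weight_profile(dataset, responses)
    pd.DataFrame(
        {
            "subject": profile.subject,
            "bin": np.arange(1, profile.n_bins + 1),
            "beta_A": profile.beta_a,
            "beta_V": profile.beta_v,
            "w_A": profile.w_a,
            "mean_sigma": profile.mean_sigma,
        }
    ).to_csv(out / "weights.csv", index=False)

    results: dict = {"config_digest": config.digest}
    if config.fit:
        logger.info("stage=fit seed=%d t=%.2fs", config.seed_fit,
                    time.perf_counter() - t0)
        cfg = fitting.MHConfig(
            n_chains=config.fit_chains,
            n_steps=config.fit_steps,
            thin=config.fit_thin,
            n_samples=config.fit_n_samples,
        )
        fit = fitting.mh_fit(dataset, responses, config.model, cfg, config.seed_fit)
        results["fit"] = {
            "medians": fit.medians,
            "waic": fit.waic,
            "rhat": fit.rhat,
            "acceptance_rate": fit.acceptance_rate,
            "warnings": fit.warnings,
        }
        (out / "fit.json").write_text(json.dumps(results["fit"], indent=2))

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_digest": config.digest,
        "files": {f: _checksum(out / f) for f in files},
        "n_trials": len(dataset),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out
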