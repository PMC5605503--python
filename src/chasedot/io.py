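"""Configuration, file round-tripping and the end-to-end pipeline.

All pipeline randomness flows from a single master seed through named
``numpy.random.SeedSequence`` sub-streams, so a run is fully reproducible
from its config file. Outputs are plain CSV/JSON (UTF-8, comma separator,
'.' decimal) stamped with the config hash and master seed.
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
import yaml

from . import analysis, design, observer, stimulus
from .cues import CueTrack, color_track, eye_track
from .exceptions import InvalidParameterError

__all__ = [
    "RunConfig",
    "run_pipeline",
    "trajectory_to_frame",
    "write_trajectory",
    "read_trajectory",
    "cues_to_frame",
]

log = logging.getLogger("chasedot")


@dataclass(frozen=True)
class RunConfig:
    """One document describing a full synthetic study."""

    sim: stimulus.SimConfig = field(default_factory=stimulus.SimConfig)
    glmm: observer.GlmmParams = field(default_factory=observer.GlmmParams)
    n_per_group: int = 24
    master_seed: int = 0
    save_trajectories: int = 0  # how many example trajectories to write

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        return cls(
            sim=stimulus.SimConfig(**doc.get("sim", {})),
            glmm=observer.GlmmParams(**doc.get("glmm", {})),
            n_per_group=doc.get("n_per_group", 24),
            master_seed=doc.get("master_seed", 0),
            save_trajectories=doc.get("save_trajectories", 0),
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def rng(self, stage: str) -> np.random.Generator:
        """Named deterministic sub-stream of the master seed."""
        key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.master_seed, spawn_key=(key,))
        )


# ---------------------------------------------------------------------------
# trajectory / cue files

def trajectory_to_frame(traj: stimulus.Trajectory, trial_id: str = "trial") -> pd.DataFrame:
    """Long-format table: one row per frame per dot."""
    F, D = traj.n_frames, traj.n_dots
    frames = np.repeat(np.arange(F), D)
    dots = np.tile(np.arange(D), F)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "frame": frames,
            "dot_id": dots,
            "role": [traj.roles[d] for d in dots],
            "x_deg": traj.positions.reshape(F * D, 2)[:, 0],
            "y_deg": traj.positions.reshape(F * D, 2)[:, 1],
            "heading_deg": traj.headings.reshape(F * D),
            "override": traj.override_log.reshape(F * D),
            "update": traj.update_log.reshape(F * D),
            "reflect": traj.reflect_log.reshape(F * D),
        }
    )


def write_trajectory(traj: stimulus.Trajectory, path: str | Path,
                     trial_id: str = "trial") -> None:
    """Write the trajectory CSV plus a JSON sidecar holding spec and config.

    The sidecar uses plain ``json`` float serialization (repr-based), so a
    read/write round trip reproduces every value exactly.
    """
    path = Path(path)
    trajectory_to_frame(traj, trial_id).to_csv(path, index=False)
    sidecar = {
        "spec": dataclasses.asdict(traj.spec),
        "config": dataclasses.asdict(traj.config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path: str | Path) -> stimulus.Trajectory:
    """Reconstruct a :class:`~chasedot.stimulus.Trajectory` written by
    :func:`write_trajectory`."""
    path = Path(path)
    # round_trip parsing keeps the CSV <-> memory mapping exact
    table = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = stimulus.TrialSpec(**sidecar["spec"])
    config = stimulus.SimConfig(**sidecar["config"])
    F = int(table["frame"].max()) + 1
    D = int(table["dot_id"].max()) + 1
    table = table.sort_values(["frame", "dot_id"])
    roles = tuple(table["role"].iloc[:D])
    return stimulus.Trajectory(
        positions=table[["x_deg", "y_deg"]].to_numpy().reshape(F, D, 2),
        headings=table["heading_deg"].to_numpy().reshape(F, D),
        roles=roles,
        update_log=table["update"].to_numpy(bool).reshape(F, D),
        override_log=table["override"].to_numpy(bool).reshape(F, D),
        reflect_log=table["reflect"].to_numpy(bool).reshape(F, D),
        spec=spec,
        config=config,
    )


def cues_to_frame(cues: CueTrack, trial_id: str = "trial") -> pd.DataFrame:
    F, D = cues.values.shape
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "frame": np.repeat(np.arange(F), D),
            "dot_id": np.tile(np.arange(D), F),
            "cue_kind": cues.kind,
            "value": cues.values.reshape(F * D),
        }
    )


def make_cues(traj: stimulus.Trajectory,
              rng: np.random.Generator | None = None) -> CueTrack | None:
    """Cue track appropriate to the trial's condition (None for baseline)."""
    if traj.spec.condition == "social":
        return eye_track(traj)
    if traj.spec.condition == "nonsocial":
        return color_track(traj, rng)
    return None


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute design → cohort → responses → fit → summaries.

    Writes ``design.csv``, ``responses.csv``, ``fit.json``,
    ``accuracy_summary.csv``, ``dprime_summary.csv`` and ``manifest.json``
    (plus optional example trajectory files) into ``outdir`` and returns the
    in-memory bundle. Identical configs produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_participants = 2 * config.n_per_group

    table = design.build_design(n_participants, rng=config.rng("design"))
    cohort = observer.sample_cohort(config.n_per_group, config.glmm,
                                    config.rng("cohort"))
    responses = observer.simulate_study(table, cohort, config.glmm,
                                        config.rng("responses"))
    fit = analysis.fit_random_intercept_logistic(responses)
    acc = analysis.accuracy_summary(responses)
    dprime = analysis.dprime_table(responses, correction="loglinear")

    table.to_csv(outdir / "design.csv", index=False)
    responses.to_csv(outdir / "responses.csv", index=False)
    acc.to_csv(outdir / "accuracy_summary.csv", index=False)
    dprime.to_csv(outdir / "dprime_summary.csv", index=False)

    fit_doc = {
        "config_hash": config.config_hash,
        "master_seed": config.master_seed,
        "fixed_effects": fit.fixed_effects.reset_index(names="term")
        .to_dict(orient="records"),
        "sigma_u_hat": fit.sigma_u_hat,
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "n_participants": fit.n_participants,
    }
    (outdir / "fit.json").write_text(json.dumps(fit_doc, indent=1))

    n_traj = min(config.save_trajectories, len(table))
    for k in range(n_traj):
        row = table.iloc[k]
        spec = stimulus.TrialSpec(
            condition=row["condition"], subtlety=float(row["subtlety"]),
            chase_present=bool(row["chase_present"]), seed=int(row["seed"]),
        )
        traj = stimulus.simulate_trial(spec, config.sim)
        log.info(
            "trial %d: %d constraint overrides", k, int(traj.override_log.sum())
        )
        write_trajectory(traj, outdir / f"trajectory_{k:03d}.csv",
                         trial_id=f"trial_{k:03d}")

    manifest = {
        "config_hash": config.config_hash,
        "master_seed": config.master_seed,
        "config": yaml.safe_load(config.to_yaml()),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "design": table,
        "cohort": cohort,
        "responses": responses,
        "fit": fit,
        "accuracy_summary": acc,
        "dprime_summary": dprime,
    }
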