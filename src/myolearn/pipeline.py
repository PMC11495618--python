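"""Configuration, stage orchestration and tabular interchange formats.

The pipeline ties the modules into six stages — simulate, features, fit,
bf, similarity, report — each reading and writing plain tabular text in a
run directory, with a JSON manifest logging stage order, seeds, input
hashes and row counts.  Time columns are seconds on the trial clock;
positions are pixels, rightward positive.
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

from myolearn import generalisation, inference, synthetic_participant
from myolearn.emg_interface import InterfaceConfig, control_signal, cursor_from_profiles, smooth
from myolearn.synthetic_participant import Cohort, CohortConfig, RawTrial
from myolearn.trajectory_features import (
    TrialFeatures,
    extract_trial_features,
    features_to_row,
    participant_qc_table,
)

logger = logging.getLogger("myolearn")

SCHEMA_VERSION = 1

#: required columns of the tidy per-trial interchange table (TrialRecord)
REQUIRED_FEATURE_COLUMNS = (
    "participant", "congruence", "session", "block_type", "direction",
    "magnitude", "preview_time", "feedback", "epsilon", "hit_pct",
    "traj_peak_time", "order_correct", "valid",
)


class MissingInputError(FileNotFoundError):
    """An upstream stage output is absent."""

    def __init__(self, path: Path, producing_stage: str):
        super().__init__(
            f"missing input {path}: run the '{producing_stage}' stage first"
        )
        self.path = path
        self.producing_stage = producing_stage


@dataclass
class PipelineConfig:
    """Resolved configuration of one run; written next to the outputs."""

    seed: int = 0
    outdir: str = "runs/default"
    schema_version: int = SCHEMA_VERSION
    cohort: dict = field(default_factory=dict)     # CohortConfig overrides
    sampler: dict = field(default_factory=dict)    # SamplerConfig overrides
    session_a: int = 1   # Bayes-factor comparison endpoints
    session_b: int = 5

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**self.cohort)

    def sampler_config(self, seed_offset: int = 0) -> inference.SamplerConfig:
        kw = dict(self.sampler)
        kw.setdefault("seed", self.seed + seed_offset)
        return inference.SamplerConfig(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unknown config schema version {version!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# feature extraction over a cohort

def process_raw_trial(
    trial: RawTrial,
    calibrations,
) -> TrialFeatures:
    """Run one raw trial through the full interface + feature chain."""
    iface = InterfaceConfig.for_group(trial.congruence, fs=trial.fs)
    profiles = {}
    for ch, raw in (("hand", trial.hand_raw), ("shin", trial.shin_raw)):
        smoothed = smooth(raw, "triangular-256")
        profiles[ch] = control_signal(smoothed, calibrations[ch], ch, trial.fs)
    traj = cursor_from_profiles(profiles["hand"], profiles["shin"], iface)
    return extract_trial_features(
        profiles["hand"], profiles["shin"], traj,
        trial.condition.path, trial.congruence,
    )


def extract_cohort_features(cohort: Cohort) -> pd.DataFrame:
    """One tidy row per trial of the cohort: schedule metadata, generating
    latents and all extracted features.

    Adds the model-index aliases ``scale`` (path magnitude) and ``day``
    (session).
    """
    rows = []
    for _, mrow in cohort.manifest.iterrows():
        trial = cohort.render(mrow)
        feats = process_raw_trial(trial, cohort.calibrations[trial.participant])
        row = mrow.to_dict()
        row.update(features_to_row(feats))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["scale"] = df["magnitude"]
    df["day"] = df["session"]
    return df


# ---------------------------------------------------------------------------
# raw-trial export / import (TrialRecord interchange)

def export_trials(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as a directory of per-trial raw files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for i, row in manifest.iterrows():
        trial = cohort.render(row)
        fname = f"trial_{i:06d}.csv"
        frame = pd.DataFrame({
            "hand_raw": trial.hand_raw,
            "shin_raw": trial.shin_raw,
        })
        header = f"# fs={trial.fs} participant={trial.participant}\n"
        with open(outdir / fname, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
        paths.append(fname)
    manifest["file"] = paths
    manifest["fs"] = cohort.config.fs
    manifest["schema_version"] = SCHEMA_VERSION
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


REQUIRED_MANIFEST_COLUMNS = (
    "participant", "congruence", "session", "direction", "magnitude",
    "preview_time", "feedback", "file", "fs", "schema_version",
)


def import_external_trials(path: str | Path) -> tuple[pd.DataFrame, list]:
    """Load a directory of trial files + manifest into the internal schema.

    Returns the validated manifest (extra columns preserved) and a loader
    list of (row, callable) pairs producing the raw channel arrays.
    Schema violations are reported per row with row identifiers.
    """
    path = Path(path)
    mpath = path / "manifest.csv"
    if not mpath.exists():
        raise MissingInputError(mpath, "export")
    manifest = pd.read_csv(mpath)
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(
            f"manifest missing required column(s) {missing} "
            f"(rows 0..{len(manifest) - 1} unusable)"
        )
    versions = set(manifest["schema_version"].unique())
    if versions - {SCHEMA_VERSION}:
        raise ValueError(f"unknown manifest schema version(s) {versions}")
    errors = []
    for i, row in manifest.iterrows():
        if not (path / row["file"]).exists():
            errors.append(f"row {i}: trial file {row['file']} not found")
    if errors:
        raise ValueError("; ".join(errors))

    def loader(row):
        return pd.read_csv(path / row["file"], comment="#")

    return manifest, [(row, loader) for _, row in manifest.iterrows()]


# ---------------------------------------------------------------------------
# stage runner

STAGES = ("simulate", "features", "fit", "bf", "similarity", "report")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(path, producing_stage)
    return path


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None
) -> Path:
    """Execute the requested stages into the run directory.

    Every stage appends an entry (inputs with hashes, outputs, row counts)
    to ``manifest.json``; the resolved configuration is written next to the
    outputs.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest_path = outdir / "manifest.json"
    entries = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    )

    def log_stage(stage, inputs, outputs, **counts):
        entries.append({
            "stage": stage,
            "seed": config.seed,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": [str(p) for p in outputs],
            **counts,
        })
        manifest_path.write_text(json.dumps(entries, indent=1))

    cohort_cache: Cohort | None = None

    def get_cohort() -> Cohort:
        nonlocal cohort_cache
        if cohort_cache is None:
            cohort_cache = synthetic_participant.simulate_cohort(
                config.cohort_config(), config.seed
            )
        return cohort_cache

    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        if stage == "simulate":
            cohort = get_cohort()
            out = outdir / "cohort_manifest.csv"
            cohort.manifest.to_csv(out, index=False)
            log_stage(stage, [], [out], rows_out=len(cohort.manifest))
        elif stage == "features":
            src = _require(outdir / "cohort_manifest.csv", "simulate")
            features = extract_cohort_features(get_cohort())
            out = outdir / "features.csv"
            features.to_csv(out, index=False)
            qc = participant_qc_table(features)
            qc_out = outdir / "participant_qc.csv"
            qc.to_csv(qc_out, index=False)
            log_stage(stage, [src], [out, qc_out],
                      rows_in=len(features), rows_out=len(features),
                      excluded_participants=int(qc["exclude"].sum()))
        elif stage == "fit":
            src = _require(outdir / "features.csv", "features")
            features = pd.read_csv(src)
            test_rows = features[features["block_type"] == "test"]
            outputs = []
            for i, feat in enumerate(("epsilon", "traj_peak_time")):
                post = inference.fit_hierarchical_model(
                    test_rows, feat, config.sampler_config(seed_offset=i)
                )
                stem = outdir / f"posterior_{feat}"
                np.savez(
                    stem.with_suffix(".npz"),
                    mu=post.mu, sigma=post.sigma, mu_c=post.mu_c,
                )
                post.cells.to_csv(stem.with_suffix(".cells.csv"), index=False)
                diag = dataclasses.asdict(post.diagnostics)
                diag["groups"] = post.groups
                diag["participant_groups"] = (
                    test_rows.drop_duplicates("participant")
                    .set_index("participant")["congruence"].to_dict()
                )
                (stem.with_suffix(".diag.json")).write_text(
                    json.dumps(diag, default=str)
                )
                outputs += [stem.with_suffix(".npz")]
            log_stage(stage, [src], outputs, rows_in=len(test_rows))
        elif stage == "bf":
            src = _require(outdir / "features.csv", "features")
            for feat in ("epsilon", "traj_peak_time"):
                _require(outdir / f"posterior_{feat}.npz", "fit")
            table = session_comparison_bayes_factors(outdir, config)
            out = outdir / "bayes_factors.csv"
            table.to_csv(out, index=False)
            log_stage(stage, [src], [out], rows_out=len(table))
        elif stage == "similarity":
            src = _require(outdir / "features.csv", "features")
            features = pd.read_csv(src)
            table = generalisation.similarity_table(
                features[features["valid"].astype(bool)],
                feature_cols={
                    "hand_amplitude": "hand_peak_amplitude",
                    "shin_amplitude": "shin_peak_amplitude",
                    "hand_peak_time": "hand_peak_time",
                    "shin_peak_time": "shin_peak_time",
                },
                session5_conditions=["R1", "R3"],
                session_a=config.session_a,
                session_b=config.session_b,
            )
            out = outdir / "similarity.csv"
            table.to_csv(out, index=False)
            log_stage(stage, [src], [out], rows_out=len(table))
        elif stage == "report":
            summary = {
                "stages_run": [e["stage"] for e in entries] + ["report"],
                "seed": config.seed,
            }
            for name in ("features", "bayes_factors", "similarity"):
                f = outdir / f"{name}.csv"
                if f.exists() and f.stat().st_size > 0:
                    summary[f"{name}_rows"] = len(pd.read_csv(f))
            out = outdir / "report.json"
            out.write_text(json.dumps(summary, indent=1))
            log_stage(stage, [], [out])
    return outdir


def session_comparison_bayes_factors(
    outdir: Path, config: PipelineConfig
) -> pd.DataFrame:
    """Marginal-mean Bayes factors for a session_a -> session_b reduction,
    per feature, group and trained scale, from the stored posteriors."""
    rows = []
    for i, feat in enumerate(("epsilon", "traj_peak_time")):
        stem = Path(outdir) / f"posterior_{feat}"
        arrays = np.load(stem.with_suffix(".npz"))
        cells = pd.read_csv(stem.with_suffix(".cells.csv"))
        diag = json.loads((stem.with_suffix(".diag.json")).read_text())
        post = inference.HierarchicalPosterior(
            mu=arrays["mu"], sigma=arrays["sigma"], cells=cells,
            transform=None,
            diagnostics=inference.Diagnostics(
                rhat_max=float(diag["rhat_max"]),
                acceptance_mean=float(diag["acceptance_mean"]),
                n_draws=int(diag["n_draws"]),
                converged=bool(diag["converged"]),
            ),
            mu_c=arrays["mu_c"], groups=diag["groups"],
        )
        groups = diag["groups"]
        p2g = diag["participant_groups"]
        g_idx = {g: j for j, g in enumerate(groups)}
        group_of_cell = np.array(
            [g_idx[p2g[p]] for p in cells["participant"]]
        )
        prior = inference.sample_prior_hierarchical(
            cells, groups, group_of_cell,
            n_draws=post.mu.shape[0], seed=config.seed + 100 + i,
        )
        for group in groups:
            members = [p for p, g in p2g.items() if g == group]
            for scale in sorted(cells["scale"].unique()):
                try:
                    post_a = post.marginal_mean(scale, config.session_a, members)
                    post_b = post.marginal_mean(scale, config.session_b, members)
                    pri_a = prior.marginal_mean(scale, config.session_a, members)
                    pri_b = prior.marginal_mean(scale, config.session_b, members)
                except KeyError:
                    continue
                bf = inference.bayes_factor(
                    post_a, post_b, pri_a, pri_b,
                    hypothesis=(
                        f"mean {feat} (scale {scale}, {group}) lower in "
                        f"session {config.session_b} than {config.session_a}"
                    ),
                    min_draws=min(4000, post_a.size),
                )
                rows.append({
                    "feature": feat,
                    "group": group,
                    "scale": scale,
                    "session_a": config.session_a,
                    "session_b": config.session_b,
                    "bf10": bf.bf10,
                    "bounded": bf.bounded,
                })
    return pd.DataFrame(rows)
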