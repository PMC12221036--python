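"""Two-stage analysis pipeline: curves to PC scores, scores to states.

Mirrors the study design: (1) filter races, normalise split times into
pacing profiles and extract functional-PC scores; (2) fit the covariate-
dependent HMM to each athlete's score trajectory, select the state count by
AIC if asked, decode globally and run diagnostics.  Every intermediate
artifact is plain CSV/JSON so each stage can be inspected or re-run alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    career_summary,
    geometric_gof,
    modal_state_by_age,
    residual_rmse,
    sojourn_times,
)
from .fpca import FPCA, BSplineBasis
from .hmm import AthleteSequence, PacingStateModel, select_n_states
from .race_data import (
    Event,
    RaceRecord,
    filter_races,
    profile_from_record,
    profiles_to_frame,
    read_race_csv,
)
from .tables import MENS_COVARIATES, WOMENS_COVARIATES


def covariate_names_for(event: Event) -> tuple[str, ...]:
    return WOMENS_COVARIATES if event is Event.W_K1_500 else MENS_COVARIATES


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run."""

    input_csv: str
    output_dir: str
    event: Event = Event.W_K1_500
    n_components: int = 4
    n_basis: int | None = None
    n_states: int | None = 4
    state_range: tuple[int, int] | None = None
    n_restarts: int = 200
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500
    exclusions: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.event, str):
            self.event = Event(self.event)
        if self.n_components < 1:
            raise ValueError("need at least one principal component")
        if self.state_range is not None:
            lo, hi = self.state_range
            if not (1 <= lo <= hi <= 10):
                raise ValueError("state range must lie within 1-10")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "state_range" in raw and raw["state_range"] is not None:
            raw["state_range"] = tuple(raw["state_range"])
        if "exclusions" in raw:
            raw["exclusions"] = tuple(
                (str(a), int(i)) for a, i in raw["exclusions"]
            )
        return cls(**raw)


def scores_frame(records, results) -> pd.DataFrame:
    """Tidy per-race PC-score table with covariate labels."""
    rows = []
    for r, beta in zip(records, results.scores, strict=True):
        row = {
            "athlete_id": r.athlete_id,
            "race_index": r.race_index,
            "age_group": r.age_group.value,
            "event_type": r.event_type.value,
        }
        for k, b in enumerate(beta):
            row[f"pc{k + 1}"] = float(b)
        rows.append(row)
    return pd.DataFrame(rows)


def build_sequences(scores_df: pd.DataFrame, covariate_names) -> list[AthleteSequence]:
    """One ordered AthleteSequence per athlete from a tidy score table."""
    pc_cols = sorted(
        (c for c in scores_df.columns if c.startswith("pc")),
        key=lambda c: int(c[2:]),
    )
    names = list(covariate_names)
    seqs = []
    for athlete, grp in scores_df.groupby("athlete_id", sort=True):
        grp = grp.sort_values("race_index")
        Z = np.zeros((len(grp), len(names)))
        for t, (_, row) in enumerate(grp.iterrows()):
            if row["age_group"] in names:
                Z[t, names.index(row["age_group"])] = 1.0
            if row["event_type"] in names:
                Z[t, names.index(row["event_type"])] = 1.0
        seqs.append(
            AthleteSequence(
                athlete_id=str(athlete),
                observations=grp[pc_cols].to_numpy(float),
                covariates=Z,
                covariate_names=tuple(names),
            )
        )
    return seqs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a manifest of artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_race_csv(config.input_csv)
    if not records:
        raise ValueError(f"no race records in {config.input_csv}")
    kept = filter_races(records, exclude=config.exclusions)
    profiles = [profile_from_record(r) for r in kept]
    profiles_to_frame(kept, profiles).to_csv(out / "profiles.csv", index=False)

    basis = (
        BSplineBasis(float(config.event.distance_m), config.n_basis)
        if config.n_basis
        else None
    )
    fpca_results = FPCA(profiles, basis=basis).fit(config.n_components)
    fpca_results.model.save(out / "fpca_model.json")
    sdf = scores_frame(kept, fpca_results)
    sdf.to_csv(out / "scores.csv", index=False)

    cov_names = covariate_names_for(config.event)
    sequences = build_sequences(sdf, cov_names)

    aic_table = None
    n_states = config.n_states
    if config.state_range is not None:
        lo, hi = config.state_range
        n_states, aic_table = select_n_states(
            sequences,
            range(lo, hi + 1),
            n_restarts=config.n_restarts,
            seed=config.seed,
            tol=config.tol,
            max_iter=config.max_iter,
        )
    model = PacingStateModel(sequences, n_states)
    results = model.fit(
        n_restarts=config.n_restarts,
        seed=config.seed,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    results.params.save(out / "hmm_model.json")

    meta = {
        s.athlete_id: [
            (int(row["race_index"]), row["age_group"], row["event_type"])
            for _, row in sdf[sdf["athlete_id"] == s.athlete_id]
            .sort_values("race_index")
            .iterrows()
        ]
        for s in sequences
    }
    timeline = career_summary(sequences, results.fit_result, meta)
    timeline.to_csv(out / "decoded_states.csv", index=False)

    soj = sojourn_times(results.decoded)
    gof = {
        str(state + 1): {
            "n_runs": len(runs),
            "p_hat": geometric_gof(runs).p_hat,
            "pvalue": geometric_gof(runs).pvalue,
            "sufficient": geometric_gof(runs).sufficient,
        }
        for state, runs in sorted(soj.runs.items())
    }
    rmse = residual_rmse(results.fit_result, sequences)
    diagnostics = {
        "aic": results.aic,
        "loglik": results.loglik,
        "n_states": n_states,
        "aic_table": aic_table,
        "sojourn_geometric_gof": gof,
        "residual_rmse": rmse.to_dict(orient="records"),
    }
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1, default=float)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n\n" + fpca_results.summary() + "\n")
    modal_state_by_age(timeline).to_csv(out / "modal_states.csv", index=False)

    manifest = {
        "config": {
            **{
                k: (v.value if isinstance(v, Event) else v)
                for k, v in asdict(config).items()
            },
        },
        "seed": config.seed,
        "n_records_input": len(records),
        "n_records_kept": len(kept),
        "selected_n_states": n_states,
        "versions": {
            "kayakpace": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
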