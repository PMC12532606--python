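"""End-to-end orchestration: simulate -> preprocess -> factor -> HMM ->
meta-states -> downstream analyses, with persisted per-stage artifacts and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import read_cohort, write_cohort
from .config import GeneratorConfig, default_config
from .evolution import fit_ctmc, km_time_to_event
from .factor import SparseFactorResults, fit_pfa_cohort, score_visits
from .hmm import (
    HMMResults,
    fit_hmm,
    select_states_bic,
    sequences_from_scores,
    viterbi_decode,
)
from .preprocess import derive_pira_cohort, impute_partial_visits
from .states import (
    aggregate_meta_transitions,
    characterize_states,
    check_validation_criteria,
    group_meta_states,
    label_states,
)

log = logging.getLogger("mscourse")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "mscourse_run"
    cohort_path: str | None = None        # use an existing cohort CSV
    generator: GeneratorConfig | None = None
    seed: int = 0
    n_states: int = 8
    s_range: list[int] | None = None      # if set, BIC selection over this range
    pfa_restarts: int = 10
    hmm_restarts: int = 5
    k_max: int = 10
    epsilon: float = 0.005
    impute: bool = True
    run_evolution: bool = True
    resume: bool = False
    write_truth: bool = True

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in vars(self).items()
            if k not in ("generator",)
        }
        d["generator"] = (
            None if self.generator is None else self.generator.to_dict()
        )
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        gen = d.pop("generator", None)
        cfg = cls(**d)
        if isinstance(gen, str):
            cfg.generator = GeneratorConfig.from_yaml(gen)
        elif isinstance(gen, dict):
            cfg.generator = GeneratorConfig.from_dict(gen)
        return cfg


@dataclass
class ReportBundle:
    """In-memory handles on every artifact a pipeline run produced."""

    config: RunConfig
    cohort: pd.DataFrame
    imputed: pd.DataFrame
    loading: SparseFactorResults
    dimension_labels: list[str]
    scores: pd.DataFrame
    hmm: HMMResults
    bic_table: pd.DataFrame | None
    decoded: pd.DataFrame
    meta_map: object
    transition_summary: object
    characterization: pd.DataFrame
    validation: object
    evolution: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute all stages in order, persisting intermediate artifacts.

    Every stage is a pure function of its inputs and the seeds in ``cfg``;
    with ``resume=True`` stages whose artifact files already exist are
    reloaded instead of recomputed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    timers: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                log.info("stage %s ...", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timers[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc

        return _Timer()

    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_of = {
        "simulate": int(seeds[0].generate_state(1)[0] % (2**31 - 1)),
        "pfa": int(seeds[1].generate_state(1)[0] % (2**31 - 1)),
        "hmm": int(seeds[2].generate_state(1)[0] % (2**31 - 1)),
        "evolution": int(seeds[3].generate_state(1)[0] % (2**31 - 1)),
    }
    manifest["derived_seeds"] = seed_of

    # ------------------------------------------------------------- cohort
    cohort_file = out / "cohort.csv"
    with stage("cohort"):
        if cfg.cohort_path:
            cohort = read_cohort(cfg.cohort_path)
        elif cfg.resume and cohort_file.exists():
            cohort = read_cohort(cohort_file)
        else:
            from .simulate import generate_cohort

            gen = cfg.generator or default_config()
            cohort = generate_cohort(gen, seed=seed_of["simulate"])
        write_cohort(cohort, cohort_file, truth=cfg.write_truth)

    # ---------------------------------------------------------- preprocess
    imputed_file = out / "imputed.csv"
    with stage("preprocess"):
        if cfg.resume and imputed_file.exists():
            imputed = read_cohort(imputed_file)
        elif cfg.impute:
            imputed = impute_partial_visits(cohort)
        else:
            imputed = cohort
        write_cohort(imputed, imputed_file, truth=cfg.write_truth)

    # ----------------------------------------------------------------- pfa
    loading_file = out / "loading.json"
    with stage("pfa"):
        if cfg.resume and loading_file.exists():
            loading = SparseFactorResults.from_json(loading_file)
        else:
            loading = fit_pfa_cohort(
                cohort,
                seed=seed_of["pfa"],
                restarts=cfg.pfa_restarts,
                k_max=cfg.k_max,
            )
        loading.to_json(loading_file)
        from .factor import assign_dimensions

        dim_labels = assign_dimensions(loading)[1]
        loading.summary().to_csv(out / "loading_table.csv", float_format="%.6g")

    # --------------------------------------------------------------- scores
    with stage("scores"):
        complete = imputed.dropna(subset=[c for c in imputed.columns
                                          if c in loading.feature_names])
        scores = score_visits(loading, complete)
        _write_csv(scores, out / "scores.csv")

    # ------------------------------------------------------------------ hmm
    hmm_file = out / "hmm.json"
    with stage("hmm"):
        seqs, ids = sequences_from_scores(scores)
        bic_table = None
        if cfg.resume and hmm_file.exists():
            model = HMMResults.from_json(hmm_file)
        elif cfg.s_range:
            best, bic_table = select_states_bic(
                seqs, cfg.s_range, restarts=cfg.hmm_restarts, seed=seed_of["hmm"]
            )
            model = bic_table.attrs["fits"][best]
            _write_csv(bic_table.drop(columns=[], errors="ignore"),
                       out / "bic.csv")
        else:
            model = fit_hmm(
                seqs, cfg.n_states, restarts=cfg.hmm_restarts,
                seed=seed_of["hmm"],
            )
        model.to_json(hmm_file)

    # --------------------------------------------------------------- decode
    with stage("decode"):
        decoded = viterbi_decode(model, seqs, ids=ids)
        month_map = scores.groupby("patient_id")["month"].apply(
            lambda s: s.to_numpy()
        )
        # Align grid months (sequences are positional).
        decoded["month"] = np.concatenate([month_map[pid] for pid in ids])
        _write_csv(decoded, out / "states.csv")

    # ----------------------------------------------------------- metastates
    with stage("metastates"):
        labels = label_states(model, dim_labels, decoded, imputed)
        meta_map = group_meta_states(
            model.transition, labels, epsilon=cfg.epsilon
        )
        occupancy = decoded["state"].value_counts().sort_index()
        summary = aggregate_meta_transitions(
            model.transition, meta_map, occupancy
        )
        meta_map.to_json(out / "meta_map.json")
        summary.meta_transition.to_csv(out / "meta_transition.csv",
                                       float_format="%.6g")
        pd.DataFrame(model.transition).to_csv(
            out / "transition.csv", float_format="%.6g"
        )

    # --------------------------------------------------------- characterize
    with stage("characterize"):
        character = characterize_states(decoded, imputed, meta_map)
        _write_csv(character, out / "state_characteristics.csv")

    # ----------------------------------------------------------- validation
    with stage("validation"):
        report = check_validation_criteria(dim_labels, meta_map, summary)
        report.to_json(out / "validation.json")

    # ------------------------------------------------------------ evolution
    evo: dict = {}
    if cfg.run_evolution:
        with stage("evolution"):
            pira = derive_pira_cohort(imputed)
            baseline_meta = (
                decoded.sort_values(["patient_id", "month"])
                .groupby("patient_id")["state"]
                .first()
                .map({s + 1: m for s, m in meta_map.mapping.items()})
            )
            pira["baseline_meta"] = pira["patient_id"].map(baseline_meta)
            pira["time"] = pira["time"].astype(float)
            pira.loc[pira["time"] <= 0, "time"] = 0.5
            _write_csv(pira, out / "pira_events.csv")
            curves = km_time_to_event(
                pira, stratum_col="baseline_meta"
            )
            km_rows = []
            for label, c in curves.items():
                for t, s_, lo_, hi_ in zip(
                    c.timeline, c.survival, c.ci_lower, c.ci_upper
                ):
                    km_rows.append((label, t, s_, lo_, hi_))
            _write_csv(
                pd.DataFrame(
                    km_rows,
                    columns=["stratum", "month", "survival", "ci_low", "ci_high"],
                ),
                out / "km_pira.csv",
            )
            evo["pira"] = pira
            evo["km"] = curves

            treated = cohort.groupby("patient_id")["treated"].first()
            if treated.nunique() > 1:
                meta_paths = decoded[["patient_id", "month", "state"]].copy()
                meta_paths["meta_state"] = meta_paths["state"].map(
                    {s + 1: m for s, m in meta_map.mapping.items()}
                )
                ctmc = fit_ctmc(meta_paths, treated)
                (out / "ctmc.json").write_text(
                    json.dumps(
                        {
                            "Q": ctmc.Q.tolist(),
                            "states": ctmc.states,
                            "hazard_ratio": ctmc.hazard_ratio,
                            "hr_ci": ctmc.hr_ci,
                            "risk_reduction": ctmc.risk_reduction,
                            "rr_ci": ctmc.rr_ci,
                        },
                        indent=1,
                    )
                )
                evo["ctmc"] = ctmc

    manifest["stage_seconds"] = timers
    manifest["artifacts"] = sorted(
        {p.name for p in out.iterdir()} | {"manifest.json"}
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return ReportBundle(
        config=cfg,
        cohort=cohort,
        imputed=imputed,
        loading=loading,
        dimension_labels=dim_labels,
        scores=scores,
        hmm=model,
        bic_table=bic_table,
        decoded=decoded,
        meta_map=meta_map,
        transition_summary=summary,
        characterization=character,
        validation=report,
        evolution=evo,
        manifest=manifest,
    )
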