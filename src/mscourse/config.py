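"""Generator configuration: validation, defaults, serialization, treatment arms."""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import DIMENSIONS, FEATURES, META_STATES


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class FeatureLink:
    """Observation model for one feature.

    The latent channel ``u = loading @ scores + noise`` maps to measurement
    units as ``loc + scale * u`` (identity), ``exp(loc + scale * u)`` (log),
    ``Poisson(exp(loc + scale * u))`` (count) or ``1{u > loc}`` (binary).
    """

    kind: str
    loc: float = 0.0
    scale: float = 1.0
    round: str | None = None   # None | "half" | "int"
    clip: tuple[float, float] | None = None

    def validate(self, name: str) -> None:
        if self.kind not in ("identity", "log", "count", "binary"):
            raise ConfigError(f"unknown link kind {self.kind!r} for {name}")
        if not np.isfinite([self.loc, self.scale]).all():
            raise ConfigError(f"non-finite link parameters for {name}")


@dataclass
class GeneratorConfig:
    """Full specification of the synthetic longitudinal MS cohort."""

    n_patients: int
    n_months: int
    loading: np.ndarray            # F x K
    uniquenesses: np.ndarray       # F
    state_means: np.ndarray        # S x K
    state_covs: np.ndarray         # S x K x K
    transition: np.ndarray         # S x S, row-stochastic, per month
    initial: np.ndarray            # S
    missing_rates: np.ndarray      # F, in [0, 1]
    feature_links: dict[str, FeatureLink]
    state_meta: list[str]          # per-state meta label
    seed: int = 0
    treated: bool = False
    treatment_multiplier: float = 1.0
    relapse_duration_mean_days: float = 47.0
    features: list[str] = field(default_factory=lambda: list(FEATURES))
    dimensions: list[str] = field(default_factory=lambda: list(DIMENSIONS))

    @property
    def n_states(self) -> int:
        return len(self.initial)

    @property
    def n_dimensions(self) -> int:
        return self.loading.shape[1]

    def validate(self) -> None:
        F, K, S = len(self.features), self.n_dimensions, self.n_states
        arrays = {
            "loading": (self.loading, (F, K)),
            "uniquenesses": (self.uniquenesses, (F,)),
            "state_means": (self.state_means, (S, K)),
            "state_covs": (self.state_covs, (S, K, K)),
            "transition": (self.transition, (S, S)),
            "initial": (self.initial, (S,)),
            "missing_rates": (self.missing_rates, (F,)),
        }
        for name, (arr, shape) in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ConfigError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.isfinite(arr).all():
                raise ConfigError(f"{name} contains non-finite entries")
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-12
        ):
            raise ConfigError("transition rows must be non-negative and sum to 1")
        if np.any(self.initial < 0) or abs(self.initial.sum() - 1.0) > 1e-12:
            raise ConfigError("initial must be a probability vector")
        if np.any(self.missing_rates < 0) or np.any(self.missing_rates > 1):
            raise ConfigError("missing_rates must lie in [0, 1]")
        if np.any(self.uniquenesses <= 0):
            raise ConfigError("uniquenesses must be positive")
        for s in range(S):
            C = self.state_covs[s]
            if not np.allclose(C, C.T, atol=1e-10):
                raise ConfigError(f"state covariance {s + 1} is not symmetric")
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ConfigError(
                    f"state covariance {s + 1} is not positive definite"
                ) from exc
        if len(self.state_meta) != S or any(
            m not in META_STATES for m in self.state_meta
        ):
            raise ConfigError("state_meta must give a valid meta label per state")
        for name, link in self.feature_links.items():
            link.validate(name)
        if set(self.feature_links) != set(self.features):
            raise ConfigError("feature_links must cover exactly the features")

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        d = {
            "n_patients": int(self.n_patients),
            "n_months": int(self.n_months),
            "seed": int(self.seed),
            "treated": bool(self.treated),
            "treatment_multiplier": float(self.treatment_multiplier),
            "relapse_duration_mean_days": float(self.relapse_duration_mean_days),
            "features": list(self.features),
            "dimensions": list(self.dimensions),
            "state_meta": list(self.state_meta),
            "loading": {
                f: [float(x) for x in self.loading[i]]
                for i, f in enumerate(self.features)
            },
            "uniquenesses": {
                f: float(self.uniquenesses[i]) for i, f in enumerate(self.features)
            },
            "feature_links": {
                f: {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(link).items()
                    if v is not None
                }
                for f, link in self.feature_links.items()
            },
            "state_means": self.state_means.tolist(),
            "state_covs": self.state_covs.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "missing_rates": {
                f: float(self.missing_rates[i]) for i, f in enumerate(self.features)
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = copy.deepcopy(d)
        features = list(d.get("features", FEATURES))
        links = {}
        for f, spec in d["feature_links"].items():
            clip = spec.get("clip")
            links[f] = FeatureLink(
                kind=spec["kind"],
                loc=float(spec.get("loc", 0.0)),
                scale=float(spec.get("scale", 1.0)),
                round=spec.get("round"),
                clip=tuple(clip) if clip is not None else None,
            )
        if "state_covs" in d:
            covs = np.asarray(d["state_covs"], dtype=float)
        else:
            covs = np.stack(
                [np.diag(np.asarray(v, dtype=float)) for v in d["state_vars"]]
            )
        cfg = cls(
            n_patients=int(d["n_patients"]),
            n_months=int(d["n_months"]),
            loading=np.array([d["loading"][f] for f in features], dtype=float),
            uniquenesses=np.array(
                [d["uniquenesses"][f] for f in features], dtype=float
            ),
            state_means=np.asarray(d["state_means"], dtype=float),
            state_covs=covs,
            transition=np.asarray(d["transition"], dtype=float),
            initial=np.asarray(d["initial"], dtype=float),
            missing_rates=np.array(
                [d["missing_rates"][f] for f in features], dtype=float
            ),
            feature_links=links,
            state_meta=list(d["state_meta"]),
            seed=int(d.get("seed", 0)),
            treated=bool(d.get("treated", False)),
            treatment_multiplier=float(d.get("treatment_multiplier", 1.0)),
            relapse_duration_mean_days=float(
                d.get("relapse_duration_mean_days", 47.0)
            ),
            features=features,
            dimensions=list(d.get("dimensions", DIMENSIONS)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "GeneratorConfig":
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            setattr(new, k, v)
        new.validate()
        return new

    # ------------------------------------------------------------ helpers
    def meta_indices(self, meta: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.state_meta) if m == meta])

    def true_meta_transition(self, occupancy: np.ndarray | None = None) -> np.ndarray:
        """Meta-aggregated transition matrix implied by the configuration.

        ``occupancy`` gives per-state weights; uniform within group if omitted.
        """
        groups = [m for m in META_STATES if m in self.state_meta]
        if occupancy is None:
            occupancy = np.ones(self.n_states)
        occupancy = np.asarray(occupancy, dtype=float)
        M = np.zeros((len(groups), len(groups)))
        for gi, g in enumerate(groups):
            rows = self.meta_indices(g)
            w = occupancy[rows] / occupancy[rows].sum()
            for hi, h in enumerate(groups):
                cols = self.meta_indices(h)
                M[gi, hi] = float(w @ self.transition[np.ix_(rows, cols)].sum(axis=1))
        return M


def default_config() -> GeneratorConfig:
    """The packaged default generator (see ``data/default_generator.yaml``)."""
    text = (
        resources.files("mscourse").joinpath("data/default_generator.yaml").read_text()
    )
    return GeneratorConfig.from_dict(yaml.safe_load(text))


def apply_treatment_effect(
    config: GeneratorConfig, multiplier: float
) -> GeneratorConfig:
    """Scale transition probabilities into the active states.

    Off-diagonal entries of the transition matrix leading into asymptomatic-
    activity or relapse states are multiplied by ``multiplier``; the removed
    (or added) mass is absorbed by the diagonal, preserving row sums.  The
    returned configuration is marked as a treated arm.
    """
    if not np.isfinite(multiplier) or multiplier < 0:
        raise ConfigError("treatment multiplier must be a non-negative real")
    A = config.transition.copy()
    active = [
        i for i, m in enumerate(config.state_meta) if m in ("activity", "relapse")
    ]
    S = config.n_states
    for i in range(S):
        for j in active:
            if i == j:
                continue
            delta = A[i, j] * (multiplier - 1.0)
            A[i, j] += delta
            A[i, i] -= delta
    if np.any(A < -1e-12):
        raise ConfigError(
            "treatment multiplier pushes a diagonal entry below zero; "
            "reduce the multiplier"
        )
    A = np.clip(A, 0.0, None)
    A /= A.sum(axis=1, keepdims=True)
    return config.replace(
        transition=A, treated=True, treatment_multiplier=float(multiplier)
    )
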