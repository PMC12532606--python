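"""From fitted HMM to the clinical picture: state labels, meta-states,
aggregated transitions, state characterization, and the predefined
validation criteria.

The grouping logic mirrors how the published states were organised: the
relapse and asymptomatic-activity states are identified from their score
signatures, and the advanced block is the largest set of remaining states
that patients essentially never leave toward milder non-activity states and
never enter directly from them — entry runs through the activity states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DIMENSION_LABELS, FEATURES, META_STATES


class LabelingError(RuntimeError):
    """Ambiguous state labelling requiring manual inspection."""


@dataclass
class StateLabels:
    """Score-signature labelling of the fitted states (0-based indices)."""

    relapse_states: list[int]
    activity_states: list[int]
    severity_order: list[int]      # remaining states, mild -> severe
    severity_score: dict[int, float]

    @property
    def non_activity(self) -> list[int]:
        return list(self.severity_order)


@dataclass
class MetaStateMap:
    """State -> meta-state grouping derived from the transition structure."""

    mapping: dict[int, str]        # 0-based state index -> meta label
    severity_order: list[int]
    epsilon: float
    warning: bool = False
    violation_mass: float = 0.0

    def indices(self, meta: str) -> list[int]:
        return [s for s, m in self.mapping.items() if m == meta]

    @property
    def groups(self) -> list[str]:
        return [m for m in META_STATES if self.indices(m)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mapping": {str(k + 1): v for k, v in self.mapping.items()},
                    "severity_order": [s + 1 for s in self.severity_order],
                    "epsilon": self.epsilon,
                    "warning": self.warning,
                    "violation_mass": self.violation_mass,
                },
                fh,
                indent=1,
            )


@dataclass
class TransitionSummary:
    """Meta-aggregated transition matrix with its occupancy weights."""

    meta_transition: pd.DataFrame   # groups x groups, row-stochastic
    occupancy: pd.Series            # per-state visit counts (1-based index)
    transition: np.ndarray          # raw S x S matrix

    def cell(self, source: str, target: str) -> float:
        return float(self.meta_transition.loc[source, target])


def label_states(
    model,
    dimension_labels: list[str],
    decoded: pd.DataFrame,
    cohort: pd.DataFrame,
    tol: float = 1e-6,
) -> StateLabels:
    """Identify the relapse and asymptomatic-activity states and rank the
    rest by severity.

    The relapse state maximizes the mean relapse-dimension score and shows a
    relapse flag at the majority of its decoded visits; the activity state
    maximizes the activity score among the rest with a relapse minority;
    remaining states are ordered by mean disability-plus-brain-damage score.
    """
    S = model.n_states
    means = model.means
    rel_dims = [
        k for k, lab in enumerate(dimension_labels)
        if lab == DIMENSION_LABELS["relapse"]
    ]
    act_dims = [
        k for k, lab in enumerate(dimension_labels)
        if lab == DIMENSION_LABELS["activity"]
    ]
    sev_dims = [
        k for k, lab in enumerate(dimension_labels)
        if lab in (DIMENSION_LABELS["disability"], DIMENSION_LABELS["brain_damage"])
    ]
    if not sev_dims:
        sev_dims = list(range(means.shape[1]))

    merged = decoded.merge(
        cohort[["patient_id", "month", "relapse"]], on=["patient_id", "month"]
    )
    relapse_share = (
        merged.groupby("state")["relapse"].mean().reindex(range(1, S + 1)).fillna(0.0)
    )

    remaining = set(range(S))
    relapse_states: list[int] = []
    if rel_dims:
        score = means[:, rel_dims].mean(axis=1)
        order = np.argsort(-score)
        if S > 1 and abs(score[order[0]] - score[order[1]]) < tol:
            raise LabelingError(
                "two states tie on the relapse score; label manually"
            )
        cand = int(order[0])
        # The relapse state must actually be relapse-dominated; a degenerate
        # model (e.g. too few states) simply has no relapse state.
        if relapse_share.loc[cand + 1] > 0.5:
            relapse_states = [cand]
            remaining.discard(cand)

    activity_states: list[int] = []
    if act_dims and remaining:
        idx = np.array(sorted(remaining))
        score = means[idx][:, act_dims].mean(axis=1)
        order = np.argsort(-score)
        if len(idx) > 1 and abs(score[order[0]] - score[order[1]]) < tol:
            raise LabelingError(
                "two states tie on the activity score; label manually"
            )
        # Highest activity score among states that are not relapse-dominated.
        for j in order:
            cand = int(idx[j])
            if relapse_share.loc[cand + 1] <= 0.5:
                activity_states = [cand]
                remaining.discard(cand)
                break

    sev = {s: float(means[s, sev_dims].sum()) for s in sorted(remaining)}
    severity_order = sorted(remaining, key=lambda s: sev[s])
    return StateLabels(
        relapse_states=relapse_states,
        activity_states=activity_states,
        severity_order=severity_order,
        severity_score=sev,
    )


def group_meta_states(
    A: np.ndarray, labels: StateLabels, epsilon: float = 0.005
) -> MetaStateMap:
    """Partition non-activity states into EME and advanced blocks.

    The advanced block is the largest severity-contiguous candidate set B
    (a suffix of the severity ordering of non-activity states) such that
    every transition from B back to other non-activity states and every
    direct transition into B from other non-activity states is at most
    ``epsilon`` — entry into B only via the activity states, which must
    carry some inflow.  Restricting candidates to severity suffixes makes
    the block unique when the no-direct-transition structure is symmetric
    in both directions.  If candidates exist but none satisfies the
    conditions, the least-violating one is returned with a warning flag.
    """
    A = np.asarray(A, dtype=float)
    non_act = labels.non_activity
    act = labels.relapse_states + labels.activity_states
    mapping = {s: "relapse" for s in labels.relapse_states}
    mapping.update({s: "activity" for s in labels.activity_states})

    def violation(B: set[int]) -> float:
        other = [s for s in non_act if s not in B]
        out_mass = sum(
            max(A[b, o] - epsilon, 0.0) for b in B for o in other
        )
        in_mass = sum(
            max(A[o, b] - epsilon, 0.0) for o in other for b in B
        )
        return out_mass + in_mass

    order = labels.severity_order  # mild -> severe
    candidates = []
    for r in range(1, len(non_act)):
        Bs = set(order[-r:])
        inflow = sum(A[a, b] for a in act for b in Bs)
        if act and inflow <= epsilon:
            continue
        candidates.append((Bs, violation(Bs)))

    best: set[int] = set()
    warning = False
    viol = 0.0
    feasible = [c for c in candidates if c[1] == 0.0]
    if feasible:
        best = max(feasible, key=lambda c: len(c[0]))[0]
    elif candidates:
        best, viol = min(candidates, key=lambda c: (c[1], -len(c[0])))
        warning = True

    for s in non_act:
        mapping[s] = "advanced" if s in best else "eme"
    return MetaStateMap(
        mapping=mapping,
        severity_order=labels.severity_order,
        epsilon=epsilon,
        warning=warning,
        violation_mass=viol,
    )


def aggregate_meta_transitions(
    A: np.ndarray, meta_map: MetaStateMap, occupancy
) -> TransitionSummary:
    """Occupancy-weighted aggregation of the transition matrix by meta-state.

    ``meta[g, h] = sum_{s in g} w_s sum_{t in h} A[s, t]`` with ``w_s`` the
    occupancy share of ``s`` within its group; rows remain exactly
    stochastic.
    """
    A = np.asarray(A, dtype=float)
    occ = pd.Series(occupancy).astype(float)
    occ.index = occ.index.astype(int)
    groups = meta_map.groups
    M = np.zeros((len(groups), len(groups)))
    for gi, g in enumerate(groups):
        rows = meta_map.indices(g)
        w = occ.reindex([s + 1 for s in rows]).fillna(0.0).to_numpy()
        if w.sum() <= 0:
            raise ValueError(f"meta-group {g!r} has zero occupancy")
        w = w / w.sum()
        for hi, h in enumerate(groups):
            cols = meta_map.indices(h)
            M[gi, hi] = float(w @ A[np.ix_(rows, cols)].sum(axis=1))
    meta = pd.DataFrame(M, index=groups, columns=groups)
    return TransitionSummary(meta_transition=meta, occupancy=occ, transition=A)


def characterize_states(
    decoded: pd.DataFrame,
    cohort: pd.DataFrame,
    meta_map: MetaStateMap | None = None,
) -> pd.DataFrame:
    """Visit-weighted summaries of the original measures per (meta-)state.

    Patients are counted each time they occupy a state; statistics are
    mean, s.d., median and IQR on the measurement scale, plus the relapse
    prevalence and visit count.  States without visits yield NA rows.
    """
    df = decoded[["patient_id", "month", "state"]].merge(
        cohort, on=["patient_id", "month"]
    )
    if meta_map is not None:
        df["meta_state"] = df["state"].map(
            {s + 1: m for s, m in meta_map.mapping.items()}
        )

    def summarize(group_col: str, keys) -> pd.DataFrame:
        rows = []
        for key in keys:
            g = df[df[group_col] == key]
            row: dict = {group_col: key, "n_visits": len(g)}
            for f in FEATURES:
                v = g[f].dropna()
                row[f"{f}_mean"] = v.mean() if len(v) else np.nan
                row[f"{f}_sd"] = v.std() if len(v) > 1 else (0.0 if len(v) else np.nan)
                row[f"{f}_median"] = v.median() if len(v) else np.nan
                row[f"{f}_q25"] = v.quantile(0.25) if len(v) else np.nan
                row[f"{f}_q75"] = v.quantile(0.75) if len(v) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    n_states = int(decoded["state"].max())
    out = summarize("state", range(1, n_states + 1))
    out.insert(0, "level", "state")
    if meta_map is not None:
        meta = summarize("meta_state", meta_map.groups)
        meta.insert(0, "level", "meta_state")
        out = pd.concat(
            [out.rename(columns={"state": "group"}),
             meta.rename(columns={"meta_state": "group"})],
            ignore_index=True,
        )
    else:
        out = out.rename(columns={"state": "group"})
    return out


@dataclass
class ValidationReport:
    criterion_1: bool
    criterion_2: bool
    evidence: dict = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return self.criterion_1 and self.criterion_2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "criterion_1": self.criterion_1,
                    "criterion_2": self.criterion_2,
                    "evidence": self.evidence,
                },
                fh,
                indent=1,
            )


def check_validation_criteria(
    dimension_labels: list[str],
    meta_map: MetaStateMap,
    summary: TransitionSummary,
) -> ValidationReport:
    """Predefined qualitative validation of a fitted pipeline.

    Criterion 1: the four named MS dimensions (physical disability, brain
    damage, relapse, asymptomatic activity) are all re-identified.
    Criterion 2: the severity gradient runs from EME to advanced states with
    direct EME-to-advanced transitions at most epsilon while the route
    through the focal-inflammatory (activity/relapse) states is open.
    """
    wanted = set(DIMENSION_LABELS.values())
    crit1 = wanted.issubset(set(dimension_labels))

    eps = meta_map.epsilon
    meta = summary.meta_transition
    groups = list(meta.index)
    active = [g for g in ("activity", "relapse") if g in groups]
    evidence: dict = {"dimension_labels": list(dimension_labels), "epsilon": eps}
    if "eme" in groups and "advanced" in groups and active:
        # Entry-level epsilon scaled to the aggregate: the EME->advanced
        # cell sums one column per advanced state, so all entries at the
        # threshold give an aggregate of len(advanced) * epsilon.
        agg_eps = eps * max(len(meta_map.indices("advanced")), 1)
        direct = meta.loc["eme", "advanced"]
        into_active = float(sum(meta.loc["eme", a] for a in active))
        occ = np.array(
            [sum(summary.occupancy.get(s + 1, 0.0) for s in meta_map.indices(a))
             for a in active]
        )
        w = occ / occ.sum() if occ.sum() > 0 else np.ones(len(active)) / len(active)
        active_to_adv = float(
            sum(wi * meta.loc[a, "advanced"] for wi, a in zip(w, active))
        )
        crit2 = bool(
            direct <= agg_eps and into_active > eps and active_to_adv > eps
        )
        evidence.update(
            {
                "eme_to_advanced": float(direct),
                "aggregate_epsilon": agg_eps,
                "eme_to_active": into_active,
                "active_to_advanced": active_to_adv,
            }
        )
    else:
        crit2 = False
        evidence["missing_meta_states"] = [
            g for g in ("eme", "advanced") if g not in groups
        ]
    return ValidationReport(criterion_1=crit1, criterion_2=crit2, evidence=evidence)
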