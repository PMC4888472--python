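"""Movement-strategy classification from a fitted latent-state model.

A fitted model yields (i) the diagonal of the switching matrix Q — how
sticky each mode is — and (ii) the decoded mode sequence, from which
transitions between the two encamped modes are counted.  Simple cut-offs
on q11, q22 and q33, plus whether the animal ever left the second
encamped mode (the M2 criterion), assign one of four broad strategies:

* dispersal:   q11 > 0.95, q22 > 0.95, q33 > 0.85 and no return from mode 2
* migration:   same cut-offs but the animal departed mode 2 at least once
* nomadic:     q11 > 0.95, q22 > 0.90, q33 <= 0.85
* sedentary:   q22 <= 0.90 and q33 <= 0.90

Anything else is "uncertain" and flagged for secondary examination.
Transitions between encamped modes are counted on the run-length encoding
with exploratory runs collapsed: an animal that travels through mode 3 on
its way from mode 1 to mode 2 has made one 1->2 transition.

The cut-offs were calibrated on Bayesian posterior medians of Q under
symmetric Dirichlet(1, 1, 1) row priors, which shrink the diagonals of
sparsely occupied modes well below their maximum-likelihood values (a
mode occupied 20 days in two stints has MLE 0.90 but posterior median
~0.84).  When classification is driven by an EM fit, the rule-stage
switching probabilities are therefore the Dirichlet posterior medians
given the expected transition counts, not the raw MLEs — otherwise every
sharp point estimate of a briefly-visited exploratory mode lands above
the 0.85 cut-off and nomadism becomes undetectable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hmm import FitConfig, FitDiagnostics, LatentStateParams, StateSequence, em_fit
from .nsd import NSDSeries, compute_nsd, standardize
from .trajectory import MIN_SERIES_DAYS, Trajectory, daily_average, shift_origin

LABELS = ("dispersal", "migration", "nomadic", "sedentary")
UNCERTAIN = "uncertain"


@dataclass
class TransitionSummary:
    """Counts of encamped-mode transitions and per-mode residency."""

    n_12: float
    n_21: float
    time_in_mode: np.ndarray        # days per mode, length 3
    duration_days: float
    scaled: bool = False            # True once expressed per 365 days

    def __post_init__(self) -> None:
        self.time_in_mode = np.asarray(self.time_in_mode, dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_12": self.n_12,
            "n_21": self.n_21,
            "time_in_mode": self.time_in_mode.tolist(),
            "duration_days": self.duration_days,
            "scaled": self.scaled,
        }


@dataclass
class ClassificationResult:
    label: str
    q11: float
    q22: float
    q33: float
    departed_mode2: bool
    evidence: TransitionSummary
    evidence_per_year: TransitionSummary
    params: Optional[LatentStateParams] = None
    diagnostics: Optional[FitDiagnostics] = None
    estimator: str = "em"
    animal_id: str = ""

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "label": self.label,
            "q11": self.q11,
            "q22": self.q22,
            "q33": self.q33,
            "departed_mode2": self.departed_mode2,
            "estimator": self.estimator,
            "evidence": self.evidence.to_dict(),
            "evidence_per_year": self.evidence_per_year.to_dict(),
            "params": self.params.to_dict() if self.params else None,
        }


def _run_length_encode(modes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(values, lengths) of consecutive runs."""
    modes = np.asarray(modes)
    if modes.size == 0:
        return np.empty(0, dtype=modes.dtype), np.empty(0, dtype=int)
    change = np.flatnonzero(modes[1:] != modes[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [modes.size])))
    return modes[starts], lengths


def count_transitions(seq: StateSequence) -> TransitionSummary:
    """Count encamped-mode transitions on the decoded sequence.

    Exploratory (mode 3) runs are collapsed before counting, so travel
    between encamped ranges registers as a single transition.  Residency
    time per mode is taken from the raw per-day labels.
    """
    modes = np.asarray(seq.modes)
    runs, _ = _run_length_encode(modes)
    encamped = runs[runs != 3]
    # drop consecutive duplicates left by removing mode-3 runs
    # (1,3,1 means an excursion, not a transition)
    if encamped.size:
        keep = np.concatenate(([True], encamped[1:] != encamped[:-1]))
        encamped = encamped[keep]
    n_12 = int(np.sum((encamped[:-1] == 1) & (encamped[1:] == 2)))
    n_21 = int(np.sum((encamped[:-1] == 2) & (encamped[1:] == 1)))
    time_in_mode = np.array([np.sum(modes == m) for m in (1, 2, 3)], dtype=float)
    return TransitionSummary(
        n_12=n_12, n_21=n_21, time_in_mode=time_in_mode,
        duration_days=float(modes.size),
    )


def scale_to_year(summary: TransitionSummary) -> TransitionSummary:
    """Express counts and residency times per uniform 365-day period."""
    if summary.duration_days <= 0:
        raise ValueError("duration_days must be positive")
    f = 365.0 / summary.duration_days
    return TransitionSummary(
        n_12=summary.n_12 * f,
        n_21=summary.n_21 * f,
        time_in_mode=summary.time_in_mode * f,
        duration_days=summary.duration_days,
        scaled=True,
    )


def apply_rules(q11: float, q22: float, q33: float, departed_mode2: bool) -> str:
    """Map switching-probability diagonals and the M2 criterion to a label.

    Rules are evaluated in order (dispersal/migration, nomadic, sedentary)
    and the first match wins; trajectories matching no rule are uncertain.
    """
    for q in (q11, q22, q33):
        if not (0.0 <= q <= 1.0):
            raise ValueError("switching probabilities must lie in [0, 1]")
    if q11 > 0.95 and q22 > 0.95 and q33 > 0.85:
        return "migration" if departed_mode2 else "dispersal"
    if q11 > 0.95 and q22 > 0.90 and q33 <= 0.85:
        return "nomadic"
    if q22 <= 0.90 and q33 <= 0.90:
        return "sedentary"
    return UNCERTAIN


def rule_switching_probabilities(
    series: NSDSeries, params: LatentStateParams
) -> np.ndarray:
    """Diagonal switching probabilities on the scale the rules expect.

    Posterior medians of q_ii under a Dirichlet(1, 1, 1) prior on each row
    of Q, given the expected transition counts of the fitted model — the
    same point estimate a converged MCMC fit of the model reports.
    """
    from scipy.stats import beta as _beta

    from . import _kernels
    from .hmm import emission_matrix

    B = emission_matrix(series, params)
    _, _, xi = _kernels.forward_backward(B, params.Q, params.pi0)
    diag = np.empty(3)
    for i in range(3):
        c_ii = xi[i, i]
        c_out = xi[i].sum() - c_ii
        diag[i] = _beta.median(1.0 + c_ii, 2.0 + c_out)
    return diag


def classify_series(
    series: NSDSeries,
    config: Optional[FitConfig] = None,
    estimator: str = "em",
    gibbs_config=None,
) -> ClassificationResult:
    """Fit the latent-state model to a standardized series and classify."""
    from .hmm import decode, relabel_states

    if estimator == "em":
        params, seq, diag = em_fit(series, config)
        q11, q22, q33 = rule_switching_probabilities(series, params)
    elif estimator == "gibbs":
        from .gibbs import gibbs_fit

        res = gibbs_fit(series, gibbs_config)
        seq = decode(series, res.params, (config or FitConfig()).decode_method)
        params, seq = relabel_states(res.params, seq)
        diag = res.diagnostics
        q11, q22, q33 = np.diag(params.Q)
    else:
        raise ValueError("estimator must be 'em' or 'gibbs'")
    summary = count_transitions(seq)
    per_year = scale_to_year(summary)
    departed = summary.n_21 >= 1
    label = apply_rules(float(q11), float(q22), float(q33), departed)
    return ClassificationResult(
        label=label,
        q11=float(q11), q22=float(q22), q33=float(q33),
        departed_mode2=bool(departed),
        evidence=summary,
        evidence_per_year=per_year,
        params=params,
        diagnostics=diag,
        estimator=estimator,
        animal_id=series.animal_id,
    )


def classify_trajectory(
    traj: Trajectory,
    config: Optional[FitConfig] = None,
    estimator: str = "em",
    gibbs_config=None,
) -> ClassificationResult:
    """Full pipeline: daily averaging, NSD, standardization, fit, rules.

    A perfectly stationary animal has zero NSD range and nothing to fit;
    it is returned as sedentary with empty evidence rather than an error.
    """
    d = traj if traj.daily else daily_average(traj)
    series = compute_nsd(d)
    try:
        series = standardize(series)
    except ValueError:
        vac = TransitionSummary(
            n_12=0, n_21=0,
            time_in_mode=np.array([series.T, 0.0, 0.0]),
            duration_days=float(series.T),
        )
        return ClassificationResult(
            label="sedentary", q11=1.0, q22=0.0, q33=0.0,
            departed_mode2=False,
            evidence=vac, evidence_per_year=scale_to_year(vac),
            estimator=estimator, animal_id=traj.animal_id,
        )
    return classify_series(series, config, estimator, gibbs_config)


@dataclass
class SensitivityReport:
    offsets: List[int]
    labels: List[str]
    modal_label: str
    agreement: float


def start_sensitivity(
    traj: Trajectory,
    offsets: Sequence[int],
    config: Optional[FitConfig] = None,
    estimator: str = "em",
) -> SensitivityReport:
    """Classify the trajectory re-anchored at several later start days.

    Reports one label per valid offset, the modal label, and the fraction
    of offsets agreeing with it — a bootstrap-style check that the
    classification does not hinge on the arbitrary start of monitoring.
    """
    labels: List[str] = []
    valid: List[int] = []
    for off in offsets:
        try:
            shifted = shift_origin(traj, int(off))
        except ValueError:
            continue
        labels.append(classify_trajectory(shifted, config, estimator).label)
        valid.append(int(off))
    if not labels:
        raise ValueError("no offset leaves a usable series")
    uniq, counts = np.unique(labels, return_counts=True)
    modal = str(uniq[np.argmax(counts)])
    agreement = float(np.max(counts) / len(labels))
    return SensitivityReport(
        offsets=valid, labels=labels, modal_label=modal, agreement=agreement
    )
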