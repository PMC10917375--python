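"""Synthetic Go/NoGo cohorts with known effective-connectivity structure.

The paradigm generator reproduces a mixed block/event response-inhibition
design: two runs of 12 blocks each (six Go blocks of 18 Go trials; six
NoGo blocks of 12 Go + 6 NoGo trials, i.e. 33.3% NoGo within block).
The cohort generator layers group structure on a ground-truth
connectivity template: a sex difference on thalamic self-inhibition and
on thalamus->pallidum coupling, and a positive association between NoGo
accuracy and the NoGo modulation of the thalamus->IFG connection.  All
randomness derives from a single master seed through per-subject
substreams, so a cohort is a pure function of its specification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    NODE_LABELS,
    DCMParameters,
    ExperimentDesign,
    RegionTimeSeries,
    SimulationError,
    simulate_bold,
)

__all__ = [
    "ParadigmSpec",
    "CohortSpec",
    "SubjectRecord",
    "generate_paradigm",
    "default_truth_template",
    "generate_cohort",
    "generate_behavior",
    "synthetic_posteriors",
    "behavior_table",
    "write_events_tsv",
    "write_cohort_manifest",
]

INPUT_NAMES = ("Go", "NoGo")
GO, NOGO = 0, 1
IFG, CAU, GP, THAL = 0, 1, 2, 3


@dataclass
class ParadigmSpec:
    """Timing and composition of the Go/NoGo task.

    Block composition (18 trials per block; NoGo blocks mix 12 Go with
    6 NoGo trials) is fixed by the experimental design being emulated;
    SOA and block gap are free timing choices.
    """

    n_runs: int = 2
    blocks_per_run: int = 12
    go_blocks_per_run: int = 6
    nogo_blocks_per_run: int = 6
    trials_per_go_block: int = 18
    go_trials_per_nogo_block: int = 12
    nogo_trials_per_nogo_block: int = 6
    soa_s: float = 2.0          # trial stimulus-onset asynchrony
    block_gap_s: float = 10.0   # rest between blocks (and initial rest)
    TR: float = 2.0
    micro_per_tr: int = 16
    seed: int = 0               # block order / NoGo position randomization

    def __post_init__(self):
        if self.go_blocks_per_run + self.nogo_blocks_per_run != self.blocks_per_run:
            raise ValueError("Go + NoGo blocks must equal blocks_per_run")

    @property
    def trials_per_nogo_block(self) -> int:
        return self.go_trials_per_nogo_block + self.nogo_trials_per_nogo_block

    @property
    def block_duration_s(self) -> float:
        return self.trials_per_go_block * self.soa_s

    @property
    def run_duration_s(self) -> float:
        return (self.block_gap_s
                + self.blocks_per_run * (self.block_duration_s + self.block_gap_s))

    @property
    def n_volumes(self) -> int:
        nv = self.run_duration_s / self.TR
        return int(np.ceil(nv - 1e-9))


def generate_paradigm(spec: ParadigmSpec) -> tuple[ExperimentDesign, pd.DataFrame]:
    """Build condition input functions and the trial-level event table.

    Returns the design (block-level Go/NoGo boxcars at microtime
    resolution, mean-centered downstream) and a table of trials with
    exact, non-stochastic counts.
    """
    if spec.trials_per_nogo_block != spec.trials_per_go_block:
        # blocks of unequal length would change block duration per type
        raise ValueError("Go and NoGo blocks must hold the same trial count")
    rng = np.random.default_rng(spec.seed)
    dt = spec.TR / spec.micro_per_tr
    T = spec.n_volumes * spec.micro_per_tr
    if spec.block_duration_s + spec.block_gap_s <= spec.block_duration_s:
        raise ValueError("non-positive block gap")
    if spec.run_duration_s > spec.n_volumes * spec.TR + 1e-9:
        raise ValueError("trials overrun the scanned duration")

    inputs = np.zeros((spec.n_runs, T, 2))
    rows = []
    for run in range(spec.n_runs):
        order = (["go"] * spec.go_blocks_per_run
                 + ["nogo"] * spec.nogo_blocks_per_run)
        order = [order[i] for i in rng.permutation(len(order))]
        t = spec.block_gap_s
        for b, btype in enumerate(order):
            col = GO if btype == "go" else NOGO
            i0 = int(round(t / dt))
            i1 = int(round((t + spec.block_duration_s) / dt))
            inputs[run, i0:i1, col] = 1.0
            if btype == "go":
                types = ["go"] * spec.trials_per_go_block
            else:
                types = ["go"] * spec.go_trials_per_nogo_block \
                      + ["nogo"] * spec.nogo_trials_per_nogo_block
                types = [types[i] for i in rng.permutation(len(types))]
            for i, ttype in enumerate(types):
                rows.append({
                    "run": run, "block": b, "block_type": btype,
                    "onset": t + i * spec.soa_s, "duration": 0.0,
                    "trial_type": ttype,
                })
            t += spec.block_duration_s + spec.block_gap_s
    events = pd.DataFrame(rows)
    design = ExperimentDesign(
        inputs=inputs, input_names=INPUT_NAMES, TR=spec.TR,
        n_volumes=spec.n_volumes, microtime_dt=dt, mean_center=True,
    )
    return design, events


def default_truth_template() -> DCMParameters:
    """Group-mean generative parameters for the inhibition circuit.

    The sign pattern follows the circuit this package models: intrinsic
    coupling with inhibitory IFG->Thal and IFG->Cau, excitatory
    Cau->IFG, Cau->GP, GP->Thal and Thal->GP; NoGo modulation with
    stronger inhibitory IFG->Cau, IFG->Thal and GP->Cau than under Go;
    driving input to all four regions under NoGo but to the IFG only
    under Go.  Magnitudes are configuration values chosen for dynamical
    stability, not empirical estimates.
    """
    p = DCMParameters.zeros(4, n_modulatory=2, n_driving=2)
    A = p.A
    A[IFG, CAU] = 0.25    # Cau -> IFG  (+)
    A[CAU, IFG] = -0.25   # IFG -> Cau  (-)
    A[GP, CAU] = 0.20     # Cau -> GP   (+)
    A[GP, THAL] = 0.20    # Thal -> GP  (+)
    A[THAL, GP] = 0.20    # GP -> Thal  (+)
    A[THAL, IFG] = -0.25  # IFG -> Thal (-)
    np.fill_diagonal(A, (-0.1, -0.1, 0.1, -0.1))

    Bgo = p.B[GO]
    Bgo[CAU, IFG] = -0.05
    Bgo[THAL, IFG] = -0.05
    Bgo[CAU, GP] = 0.10
    Bgo[IFG, THAL] = 0.10
    Bgo[IFG, IFG] = 0.10
    Bgo[CAU, CAU] = -0.10

    Bnogo = p.B[NOGO]
    Bnogo[CAU, IFG] = -0.25
    Bnogo[THAL, IFG] = -0.25
    Bnogo[CAU, GP] = -0.15
    Bnogo[CAU, CAU] = -0.10
    Bnogo[THAL, THAL] = -0.10

    p.C[IFG, GO] = 0.10
    p.C[:, NOGO] = (0.15, 0.10, 0.10, 0.10)
    return p


#: the six intrinsic connections with a reported sign, as (target, source)
REPORTED_INTRINSIC = (
    (THAL, IFG),  # IFG -> Thal, negative
    (GP, THAL),   # Thal -> GP, positive
    (IFG, CAU),   # Cau -> IFG, positive
    (CAU, IFG),   # IFG -> Cau, negative
    (GP, CAU),    # Cau -> GP, positive
    (THAL, GP),   # GP -> Thal, positive
)


@dataclass
class CohortSpec:
    """Population structure of a synthetic cohort.

    ``sex_effects`` maps parameter addresses — ("A", i, j), ("B", k, i, j)
    or ("C", i, k) — to female-minus-male differences; ``performance_slopes``
    maps addresses to the change per percentage point of (mean-centered)
    NoGo accuracy.  ``subject_sd`` is the SD of iid Gaussian deviations
    added to every A/B/C entry.  ``snr`` is std(signal)/std(noise) per node.
    """

    n_subjects: int = 30
    n_female: int = 15
    template: DCMParameters = field(default_factory=default_truth_template)
    subject_sd: float = 0.05
    sex_effects: dict = field(default_factory=lambda: {
        ("A", GP, THAL): -0.10,       # females: more negative Thal -> GP
        ("B", NOGO, THAL, THAL): 0.10,  # females: greater Thal self-inhibition
    })
    performance_slopes: dict = field(default_factory=lambda: {
        ("B", NOGO, IFG, THAL): 0.003,  # NoGo accuracy ~ Thal -> IFG modulation
    })
    nogo_accuracy_mean: float = 70.34
    nogo_accuracy_sd: float = 15.6
    go_accuracy_mean: float = 98.47
    go_accuracy_sd: float = 3.4
    rt_mean_ms: float = 314.44
    age_mean: float = 21.57
    age_sd: float = 2.3
    snr: float = 1.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        for addr in set(self.sex_effects) | set(self.performance_slopes):
            _check_address(self.template, addr)


def _check_address(template: DCMParameters, addr: tuple) -> None:
    mat, idx = addr[0], addr[1:]
    arr = getattr(template, mat, None)
    if arr is None:
        raise ValueError(f"unknown parameter matrix {mat!r}")
    try:
        arr[idx]
    except (IndexError, TypeError) as exc:
        raise ValueError(f"bad parameter address {addr!r}") from exc


def _apply_shift(params: DCMParameters, addr: tuple, delta: float) -> None:
    getattr(params, addr[0])[addr[1:]] += delta


@dataclass
class SubjectRecord:
    """One simulated participant: ground truth, data and behavior."""

    subject_id: str
    sex: str                    # "F" or "M"
    age: float
    true_params: DCMParameters
    nogo_accuracy: float        # target, percent
    go_accuracy: float
    timeseries: RegionTimeSeries
    trials: pd.DataFrame

    @property
    def sex_code(self) -> float:
        return 0.5 if self.sex == "F" else -0.5


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_behavior(events: pd.DataFrame, go_accuracy: float,
                      nogo_accuracy: float, rng: np.random.Generator,
                      rt_mean_ms: float = 314.44, rt_shift_ms: float = 150.0,
                      rt_sigma: float = 0.4) -> pd.DataFrame:
    """Simulate trial-level responses at target per-condition accuracies.

    Correctness is Bernoulli per trial (correct Go = response, correct
    NoGo = withheld response).  Reaction times for responded trials are
    drawn from a shifted lognormal whose mean equals ``rt_mean_ms``.
    """
    if not (0 <= go_accuracy <= 100 and 0 <= nogo_accuracy <= 100):
        raise ValueError("target accuracies must be in [0, 100]")
    trials = events.copy()
    is_go = (trials["trial_type"] == "go").to_numpy()
    p_correct = np.where(is_go, go_accuracy / 100.0, nogo_accuracy / 100.0)
    correct = rng.random(len(trials)) < p_correct
    responded = np.where(is_go, correct, ~correct)
    mu = np.log(rt_mean_ms - rt_shift_ms) - rt_sigma ** 2 / 2
    rt = rt_shift_ms + rng.lognormal(mu, rt_sigma, size=len(trials))
    trials["correct"] = correct
    trials["response"] = responded.astype(int)
    trials["rt_ms"] = np.where(responded, rt, np.nan)
    return trials


def generate_cohort(cohort: CohortSpec, paradigm: ParadigmSpec,
                    max_redraws: int = 5) -> list[SubjectRecord]:
    """Simulate a full cohort of subjects under one paradigm.

    Per subject, true parameters are template + sex effect + performance
    slope x centered NoGo accuracy + iid Gaussian deviations; BOLD is
    simulated with per-node noise set by the cohort SNR.  Unstable
    parameter draws are redrawn up to ``max_redraws`` times, then the
    generator fails loudly.
    """
    design, events = generate_paradigm(paradigm)
    streams = np.random.SeedSequence(cohort.master_seed).spawn(cohort.n_subjects)
    acc_center = cohort.nogo_accuracy_mean
    subjects = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sex = "F" if i < cohort.n_female else "M"
        sex_code = 0.5 if sex == "F" else -0.5
        age = _truncated_normal(rng, cohort.age_mean, cohort.age_sd, 16, 35)
        nogo_acc = _truncated_normal(rng, cohort.nogo_accuracy_mean,
                                     cohort.nogo_accuracy_sd, 1, 100)
        go_acc = _truncated_normal(rng, cohort.go_accuracy_mean,
                                   cohort.go_accuracy_sd, 50, 100)
        base = DCMParameters(
            A=cohort.template.A.copy(), B=cohort.template.B.copy(),
            C=cohort.template.C.copy(), hemo=cohort.template.hemo,
            node_labels=cohort.template.node_labels,
        )
        for addr, eff in cohort.sex_effects.items():
            _apply_shift(base, addr, sex_code * eff)
        for addr, slope in cohort.performance_slopes.items():
            _apply_shift(base, addr, slope * (nogo_acc - acc_center))

        for attempt in range(max_redraws + 1):
            params = DCMParameters(
                A=base.A + rng.normal(0, cohort.subject_sd, base.A.shape),
                B=base.B + rng.normal(0, cohort.subject_sd, base.B.shape),
                C=base.C + rng.normal(0, cohort.subject_sd, base.C.shape),
                hemo=base.hemo, node_labels=base.node_labels,
            )
            try:
                clean = simulate_bold(params, design)
                break
            except SimulationError:
                if attempt == max_redraws:
                    raise SimulationError(
                        f"subject {i}: no stable parameter draw within "
                        f"{max_redraws} redraws (subject_sd={cohort.subject_sd})"
                    )
        noise_sd = clean.values.std(axis=0) / cohort.snr
        noise_sd = np.maximum(noise_sd, 1e-6)
        params.noise_log_precisions = -2.0 * np.log(noise_sd)
        noisy = clean.values + rng.normal(size=clean.values.shape) * noise_sd
        ts = RegionTimeSeries(
            values=noisy, TR=clean.TR, run_starts=clean.run_starts,
            node_labels=clean.node_labels,
            metadata=dict(clean.metadata) | {"snr": cohort.snr, "subject": i},
        )
        trials = generate_behavior(events, go_acc, nogo_acc, rng,
                                   rt_mean_ms=cohort.rt_mean_ms)
        subjects.append(SubjectRecord(
            subject_id=f"sub-{i:03d}", sex=sex, age=age, true_params=params,
            nogo_accuracy=nogo_acc, go_accuracy=go_acc,
            timeseries=ts, trials=trials,
        ))
    return subjects


def synthetic_posteriors(subjects: list[SubjectRecord], priors=None,
                         error_sd: float = 0.05, seed: int = 0) -> list:
    """First-level posteriors emulated directly from subject ground truth.

    Each subject's posterior mean is the true parameter vector plus iid
    Gaussian estimation error of SD ``error_sd`` and the posterior
    covariance is ``error_sd**2 I`` (over free parameters).  This is a
    fast, well-calibrated stand-in for full model inversion, used to
    exercise the group-level (PEB/BMR/BMA) machinery at scale.
    """
    from .variational_inversion import PosteriorEstimate, PriorSpec

    if priors is None:
        priors = PriorSpec.default(n_nodes=subjects[0].true_params.n_nodes)
    pm = priors.param_map
    free = priors.variance > 0
    rng = np.random.default_rng(seed)
    out = []
    for s in subjects:
        true = pm.pack(s.true_params)
        mean = true.copy()
        mean[free] += rng.normal(0, error_sd, free.sum())
        cov = np.zeros((len(pm), len(pm)))
        cov[np.ix_(free, free)] = np.eye(free.sum()) * error_sd ** 2
        out.append(PosteriorEstimate(
            mean=mean, cov=cov, free_energy=0.0,
            f_trace=np.array([0.0]), converged=True,
            noise_log_precisions=s.true_params.noise_log_precisions,
            explained_variance=None, param_map=pm, prior=priors,
            diagnostics={"synthetic": True}))
    return out


def behavior_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject behavioral summary (realized, not target, accuracies)."""
    rows = []
    for s in subjects:
        t = s.trials
        go = t[t.trial_type == "go"]
        nogo = t[t.trial_type == "nogo"]
        rt = go.loc[go.correct, "rt_ms"]
        rows.append({
            "subject_id": s.subject_id, "sex": s.sex, "age": s.age,
            "go_accuracy": 100.0 * go.correct.mean(),
            "nogo_accuracy": 100.0 * nogo.correct.mean(),
            "go_rt_ms": rt.mean(),
        })
    return pd.DataFrame(rows)


def write_events_tsv(trials: pd.DataFrame, path: str | Path) -> None:
    """Events in a BIDS-style TSV (onset, duration, trial_type, ...)."""
    cols = ["onset", "duration", "trial_type"]
    extra = [c for c in ("response", "rt_ms", "run", "block") if c in trials]
    trials[cols + extra].to_csv(path, sep="\t", index=False, na_rep="n/a")


def write_cohort_manifest(subjects: list[SubjectRecord], directory: str | Path,
                          cohort: CohortSpec | None = None) -> Path:
    """Write per-subject data files plus a JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in subjects:
        ts_path = directory / f"{s.subject_id}_bold.tsv"
        par_path = directory / f"{s.subject_id}_truth.json"
        ev_path = directory / f"{s.subject_id}_events.tsv"
        s.timeseries.to_tsv(ts_path)
        s.true_params.to_json(par_path)
        write_events_tsv(s.trials, ev_path)
        entries.append({
            "subject_id": s.subject_id, "sex": s.sex, "age": s.age,
            "nogo_accuracy": s.nogo_accuracy, "go_accuracy": s.go_accuracy,
            "bold": ts_path.name, "truth": par_path.name, "events": ev_path.name,
        })
    manifest = {
        "n_subjects": len(subjects),
        "master_seed": None if cohort is None else cohort.master_seed,
        "subjects": entries,
    }
    out = directory / "cohort.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out
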