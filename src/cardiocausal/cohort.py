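"""Synthetic ECG/PPG cohorts with a known, planted causal structure.

Real oscillometric-protocol cohorts pairing single-lead ECG with wrist PPG
and clinician-adjudicated hypertension labels are access-restricted, so this
module generates stand-ins at two levels:

* **waveform level** (:func:`simulate_waveform_cohort`) - per-subject ECG
  (template QRS at scheduled beat times) and PPG (two-Gaussian pulse:
  systolic wave plus dicrotic wave) segments.  Hypertension causally shifts
  the dicrotic wave earlier, which shortens the late-systolic timing
  features (in particular the sdPPG-c-to-dPPG-valley duration), while a
  latent "vascular tone" confounder drives both the label and non-causal
  amplitude/heart-rate features, inducing spurious correlations.
* **feature level** (:func:`simulate_feature_sem`) - direct sampling from a
  structural equation model over named feature variables plus a binary
  label, for fast tests of the causal-discovery stages.

Effect sizes are specified as standardized between-class mean shifts (in
units of the within-class SD); logistic-link coefficients are calibrated
numerically so the realized shift matches the requested one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .waveforms import WaveformRecord

__all__ = [
    "CohortSpec",
    "PlantedDag",
    "NodeEquation",
    "simulate_waveform_cohort",
    "simulate_feature_sem",
    "hypertension_feature_dag",
    "pulse_waveform",
    "pulse_landmark_times",
    "write_cohort_csv",
    "read_cohort_csv",
]


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the emulated oscillometric protocol: 405 subjects of
    whom 183 are hypertensive, 24-36 segments per subject, 15-30 s per
    segment.  ``causal_effect`` is the standardized shift of the causally
    linked dicrotic-timing parameter between classes; ``confounder_effect``
    is the standardized label-shift of the latent confounder driving
    non-causal features.
    """

    n_subjects: int = 405
    prevalence: float = 183 / 405
    segments_per_subject: tuple[int, int] = (24, 36)
    segment_duration_s: tuple[float, float] = (15.0, 30.0)
    sampling_rate_hz: float = 125.0
    heart_rate_bpm: tuple[float, float] = (55.0, 90.0)
    causal_effect: float = 1.0
    confounder_effect: float = 1.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        for name in ("segments_per_subject", "segment_duration_s", "heart_rate_bpm"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range is empty ({lo!r} > {hi!r})")
        if self.segments_per_subject[0] < 1:
            raise ValueError("segments_per_subject must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        for name in ("causal_effect", "confounder_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# logistic-link calibration
# ---------------------------------------------------------------------------

_HERM_X, _HERM_W = np.polynomial.hermite_e.hermegauss(80)
_HERM_W = _HERM_W / math.sqrt(2 * math.pi)  # E[f(U)], U ~ N(0,1)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _gauss_mean(f) -> float:
    return float(np.sum(_HERM_W * f(_HERM_X)))


def _intercept_for_prevalence(gamma: float, prevalence: float) -> float:
    if gamma == 0.0:
        return math.log(prevalence / (1 - prevalence))
    fn = lambda a: _gauss_mean(lambda u: _sigmoid(a + gamma * u)) - prevalence
    return optimize.brentq(fn, -40, 40, xtol=1e-12)


def _class_shift(gamma: float, prevalence: float) -> float:
    """E[U | L=1] - E[U | L=0] for L ~ Bernoulli(sigmoid(a + gamma*U))."""
    if gamma == 0.0:
        return 0.0
    a = _intercept_for_prevalence(gamma, prevalence)
    m = _gauss_mean(lambda u: u * _sigmoid(a + gamma * u))
    return m / prevalence + m / (1 - prevalence)


def logistic_coef_for_shift(shift: float, prevalence: float = 0.5) -> float:
    """Logistic coefficient on a standard-normal cause realizing a given
    standardized between-class mean shift of that cause.

    The shift saturates at phi(z_p) / (p (1-p)) (a hard threshold on the
    cause); requesting more raises ``ValueError``.
    """
    if shift == 0.0:
        return 0.0
    from scipy.special import ndtri

    z = float(ndtri(prevalence))
    cap = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi) / (prevalence * (1 - prevalence))
    if shift >= 0.985 * cap:
        raise ValueError(
            f"requested shift {shift:.3f} exceeds the logistic-link ceiling "
            f"{cap:.3f} at prevalence {prevalence:.3f}"
        )
    fn = lambda g: _class_shift(g, prevalence) - shift
    return optimize.brentq(fn, 1e-9, 200.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# feature-level structural equation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeEquation:
    """Structural equation of one node: linear-Gaussian or logistic-Bernoulli."""

    parents: dict[str, float] = field(default_factory=dict)
    link: str = "linear"  # "linear" | "logistic"
    noise_sd: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.link not in ("linear", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PlantedDag:
    """Ground-truth DAG with per-node structural equations.

    ``label`` names the binary node (logistic link).  The edge list is
    derived from the equations; acyclicity is validated on construction.
    """

    equations: dict[str, NodeEquation]
    label: str

    def __post_init__(self) -> None:
        if self.label not in self.equations:
            raise ValueError(f"label node {self.label!r} has no equation")
        if self.equations[self.label].link != "logistic":
            raise ValueError("label node must use the logistic link")
        for child, eq in self.equations.items():
            for p in eq.parents:
                if p not in self.equations:
                    raise ValueError(f"parent {p!r} of {child!r} has no equation")
        self.topological_order()  # raises listing the cycle

    @property
    def nodes(self) -> list[str]:
        return list(self.equations)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (p, c)
            for c, eq in self.equations.items()
            for p, coef in eq.parents.items()
            if coef != 0.0
        )

    def topological_order(self) -> list[str]:
        indeg = {v: 0 for v in self.equations}
        children: dict[str, list[str]] = {v: [] for v in self.equations}
        for c, eq in self.equations.items():
            for p in eq.parents:
                indeg[c] += 1
                children[p].append(c)
        queue = sorted(v for v, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in sorted(children[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) < len(self.equations):
            cycle = sorted(v for v, d in indeg.items() if d > 0)
            raise ValueError(f"structural equations contain a cycle among {cycle}")
        return order

    def adjacent_to_label(self) -> set[str]:
        out = set(self.equations[self.label].parents)
        for c, eq in self.equations.items():
            if self.label in eq.parents and eq.parents[self.label] != 0.0:
                out.add(c)
        return {v for v in out if v != self.label}


def simulate_feature_sem(
    dag: PlantedDag, n: int, seed: int
) -> tuple[pd.DataFrame, PlantedDag]:
    """Draw ``n`` samples from the structural equations in topological order.

    Continuous nodes are linear-Gaussian; the label is Bernoulli with a
    logistic link on its parents.  Returns the data together with the
    ground-truth DAG.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in dag.topological_order():
        eq = dag.equations[v]
        eta = np.full(n, eq.intercept, dtype=float)
        for p, coef in eq.parents.items():
            eta += coef * cols[p]
        if eq.link == "logistic":
            cols[v] = (rng.random(n) < _sigmoid(eta)).astype(float)
        else:
            cols[v] = eta + eq.noise_sd * rng.standard_normal(n)
    return pd.DataFrame({v: cols[v] for v in dag.nodes}), dag


def hypertension_feature_dag(
    causal_effect: float = 1.0,
    confounder_effect: float = 1.2,
    prevalence: float = 0.5,
    n_noise: int = 5,
    spur_loading: float = 0.9,
) -> PlantedDag:
    """The planted feature-level cohort structure.

    ``conf`` (a measured vascular-tone feature) raises hypertension risk and
    loads on the spurious feature ``f_spur``; hypertension in turn shifts
    the causal timing feature ``f_causal`` by ``causal_effect`` within-class
    SDs.  ``f_noise_*`` are independent distractors.  The label's causal
    neighbourhood is therefore {conf, f_causal}, while ``f_spur`` is merely
    correlated with the label through the confounder - the discrimination
    the causal-feature pipeline is meant to make.
    """
    gamma = logistic_coef_for_shift(confounder_effect, prevalence)
    alpha = _intercept_for_prevalence(gamma, prevalence)
    eqs: dict[str, NodeEquation] = {
        "conf": NodeEquation(),
        "label": NodeEquation(
            parents={"conf": gamma} if gamma else {},
            link="logistic",
            intercept=alpha,
        ),
        "f_causal": NodeEquation(
            parents={"label": causal_effect} if causal_effect else {}, noise_sd=1.0
        ),
        "f_spur": NodeEquation(
            parents={"conf": spur_loading} if spur_loading else {},
            noise_sd=math.sqrt(max(1.0 - spur_loading**2, 0.05)),
        ),
    }
    for j in range(n_noise):
        eqs[f"f_noise_{j + 1}"] = NodeEquation()
    return PlantedDag(equations=eqs, label="label")


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

#: subject-to-subject SD of the dicrotic delay (s); the causal effect is
#: expressed in units of this spread
TAU2_SD = 0.03
_BASE_PULSE = dict(mu1=0.13, s1=0.055, a1=1.0, mu2=0.42, s2=0.09, a2=0.35)


def pulse_waveform(t: np.ndarray, params: dict) -> np.ndarray:
    """Closed-form two-Gaussian pulse (systolic + dicrotic wave).

    ``params``: onset (s), mu1/s1/a1 of the systolic wave and mu2/s2/a2 of
    the dicrotic wave, offsets relative to onset.
    """
    u = np.asarray(t, dtype=float) - params["onset"]
    g1 = params["a1"] * np.exp(-0.5 * ((u - params["mu1"]) / params["s1"]) ** 2)
    g2 = params["a2"] * np.exp(-0.5 * ((u - params["mu2"]) / params["s2"]) ** 2)
    return g1 + g2


def _pulse_d1(t: np.ndarray, params: dict) -> np.ndarray:
    u = np.asarray(t, dtype=float) - params["onset"]
    out = np.zeros_like(u)
    for mu, s, a in (
        (params["mu1"], params["s1"], params["a1"]),
        (params["mu2"], params["s2"], params["a2"]),
    ):
        z = (u - mu) / s
        out += -a * z / s * np.exp(-0.5 * z * z)
    return out


def _pulse_d2(t: np.ndarray, params: dict) -> np.ndarray:
    u = np.asarray(t, dtype=float) - params["onset"]
    out = np.zeros_like(u)
    for mu, s, a in (
        (params["mu1"], params["s1"], params["a1"]),
        (params["mu2"], params["s2"], params["a2"]),
    ):
        z = (u - mu) / s
        out += a * (z * z - 1.0) / (s * s) * np.exp(-0.5 * z * z)
    return out


def pulse_landmark_times(params: dict, next_onset: float, grid_hz: float = 20000.0) -> dict[str, float]:
    """Landmark times of the closed-form pulse, located on a dense grid of
    the analytic signal and its exact derivatives.

    Serves as the generator-side ground truth against which the sampled-
    signal detector can be checked.  ``next_onset`` is the onset time of the
    following pulse (the search horizon).
    """
    t0 = params["onset"]
    t = np.arange(t0, next_onset, 1.0 / grid_hz)
    p = pulse_waveform(t, params)
    d1 = _pulse_d1(t, params)
    d2 = _pulse_d2(t, params)

    def amax(x, lo, hi):
        i, j = np.searchsorted(t, lo), np.searchsorted(t, hi)
        return float(t[i + int(np.argmax(x[i:j]))])

    def amin(x, lo, hi):
        i, j = np.searchsorted(t, lo), np.searchsorted(t, hi)
        return float(t[i + int(np.argmin(x[i:j]))])

    horizon = float(t[-1])
    peak = amax(p, t0 + 0.02, t0 + params["mu2"])
    valley = float(t0)
    dp = amax(d1, valley, peak)
    a = amax(d2, valley, dp)
    b = amin(d2, dp, peak)
    c = amax(d2, peak, horizon)
    d = amin(d2, c, horizon)
    dv = amin(d1, d, horizon)
    e = amax(d2, dv, horizon)
    f = amin(d2, e, horizon)
    return {
        "ppg_valley": valley,
        "sdppg_a": a,
        "dppg_peak": dp,
        "sdppg_b": b,
        "ppg_peak": peak,
        "sdppg_c": c,
        "sdppg_d": d,
        "dppg_valley": dv,
        "sdppg_e": e,
        "sdppg_f": f,
    }


def simulate_waveform_cohort(spec: CohortSpec) -> list[WaveformRecord]:
    """Generate the synthetic waveform cohort.

    Per subject: a latent confounder ``u`` raises hypertension risk (by
    ``confounder_effect`` standardized units) and also elevates heart rate
    and PPG amplitude; the hypertension label shifts the subject's dicrotic
    delay earlier by ``causal_effect`` x :data:`TAU2_SD` seconds.  Beat
    schedules and per-beat pulse parameters are recorded in each record's
    ``meta`` as ground truth.  Identical specs (same seed) reproduce the
    cohort bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    gamma = logistic_coef_for_shift(spec.confounder_effect, spec.prevalence)
    alpha = _intercept_for_prevalence(gamma, spec.prevalence)
    records: list[WaveformRecord] = []
    for s in range(spec.n_subjects):
        u = rng.standard_normal()
        label = int(rng.random() < _sigmoid(alpha + gamma * u))
        hr = rng.uniform(*spec.heart_rate_bpm) + 3.0 * u
        hr = float(np.clip(hr, 40.0, 140.0))
        ptt0 = 0.20 + 0.015 * rng.standard_normal()
        amp0 = 1.0 + 0.10 * u + 0.05 * rng.standard_normal()
        tau2 = (
            _BASE_PULSE["mu2"]
            + TAU2_SD * rng.standard_normal()
            - spec.causal_effect * TAU2_SD * label
        )
        n_seg = int(rng.integers(spec.segments_per_subject[0], spec.segments_per_subject[1] + 1))
        segments, beat_times_all, pulse_params_all = [], [], []
        for _ in range(n_seg):
            dur = rng.uniform(*spec.segment_duration_s)
            n_samp = int(round(dur * fs))
            tgrid = np.arange(n_samp) / fs
            beats = []
            tb = 0.4 + 0.1 * rng.random()
            while tb < dur - 0.8:
                beats.append(tb)
                tb += 60.0 / hr * (1.0 + 0.03 * rng.standard_normal())
            beats = np.asarray(beats)
            ecg = np.zeros(n_samp)
            ppg = np.zeros(n_samp)
            params_seg = []
            for bt in beats:
                qrs_amp = 1.0 + 0.05 * rng.standard_normal()
                z = (tgrid - bt) / 0.02
                ecg += qrs_amp * (1.0 - z * z) * np.exp(-0.5 * z * z)
                params = dict(
                    onset=bt + ptt0 + 0.004 * rng.standard_normal(),
                    mu1=_BASE_PULSE["mu1"],
                    s1=_BASE_PULSE["s1"],
                    a1=amp0 * (1.0 + 0.03 * rng.standard_normal()),
                    mu2=tau2 + 0.005 * rng.standard_normal(),
                    s2=_BASE_PULSE["s2"],
                    a2=0.35 * amp0 * (1.0 + 0.05 * rng.standard_normal()),
                )
                ppg += pulse_waveform(tgrid, params)
                params_seg.append(params)
            ecg += spec.noise_sd * rng.standard_normal(n_samp)
            ppg += spec.noise_sd * rng.standard_normal(n_samp)
            segments.append((ecg, ppg))
            beat_times_all.append(beats)
            pulse_params_all.append(params_seg)
        records.append(
            WaveformRecord(
                subject_id=f"S{s:04d}",
                sampling_rate_hz=fs,
                segments=segments,
                label=label,
                meta={
                    "confounder": float(u),
                    "heart_rate_bpm": hr,
                    "tau2_s": float(tau2),
                    "beat_times": beat_times_all,
                    "pulse_params": pulse_params_all,
                },
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def write_cohort_csv(records: list[WaveformRecord], out_dir) -> tuple[str, str]:
    """Long-format waveform CSV plus a label CSV.

    ``waveforms.csv``: subject_id, segment_id, time_s, ecg, ppg.
    ``labels.csv``: subject_id, hypertension.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for rec in records:
        fs = rec.sampling_rate_hz
        for k, (ecg, ppg) in enumerate(rec.segments):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "segment_id": k,
                        "time_s": np.arange(len(ecg)) / fs,
                        "ecg": ecg,
                        "ppg": ppg,
                    }
                )
            )
    wave_path = out / "waveforms.csv"
    pd.concat(frames, ignore_index=True).to_csv(wave_path, index=False, float_format="%.6g")
    labels = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "hypertension": [r.label for r in records],
        }
    )
    label_path = out / "labels.csv"
    labels.to_csv(label_path, index=False)
    return str(wave_path), str(label_path)


def read_cohort_csv(wave_path, label_path, sampling_rate_hz: float) -> list[WaveformRecord]:
    waves = pd.read_csv(wave_path)
    labels = pd.read_csv(label_path).set_index("subject_id")["hypertension"]
    records = []
    for sid, sub in waves.groupby("subject_id", sort=True):
        segments = [
            (seg["ecg"].to_numpy(), seg["ppg"].to_numpy())
            for _, seg in sub.groupby("segment_id", sort=True)
        ]
        records.append(
            WaveformRecord(
                subject_id=str(sid),
                sampling_rate_hz=sampling_rate_hz,
                segments=segments,
                label=int(labels.loc[sid]),
            )
        )
    return records
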