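"""Nonlinear vocal phenomena: annotation tracks, affected-frame proportions,
jump rates, and the zero-one-inflated beta (ZOIB) model.

Per recording, each phenomenon (subharmonics, amplitude modulation, chaos,
fry) is summarized as the proportion of voiced frames whose centers fall in
annotated segments of that label, and sudden frequency jumps as events per
minute of voiced audio. Across recordings these proportions pile up at 0
(phenomenon absent) and occasionally 1 (entire recording affected), so they
are modeled with a zero-one-inflated beta distribution:

    P(y = 0) = zoi * (1 - coi)
    P(y = 1) = zoi * coi
    y in (0, 1): (1 - zoi) * Beta(y; mu * phi, (1 - mu) * phi)

where zoi is the probability of an inflated (exactly 0 or 1) value, coi
the conditional probability that an inflated value is 1, mu the beta mean
and phi the beta precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .pitch import PitchContour
from .synth import PHENOMENON_LABELS

__all__ = [
    "AnnotationTrack",
    "NonlinearSummary",
    "ZOIBParams",
    "phenomenon_proportions",
    "jump_rate",
    "zoib_loglik",
    "fit_zoib",
    "simulate_zoib",
    "read_annotation_csv",
    "write_annotation_csv",
]


@dataclass
class AnnotationTrack:
    """Labeled time segments plus jump-event times for one recording.

    Segments may overlap across labels but not within a label.
    """

    segments: list[tuple[float, float, str]] = field(default_factory=list)
    jumps: list[float] = field(default_factory=list)

    def __post_init__(self):
        by_label: dict[str, list[tuple[float, float]]] = {}
        for s, e, lab in self.segments:
            if s >= e:
                raise ValueError(f"AnnotationTrack: segment start {s} >= end {e}")
            if lab not in PHENOMENON_LABELS:
                raise ValueError(
                    f"AnnotationTrack: unknown label {lab!r}; valid: {PHENOMENON_LABELS}"
                )
            by_label.setdefault(lab, []).append((s, e))
        for lab, segs in by_label.items():
            segs = sorted(segs)
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"AnnotationTrack: overlapping {lab!r} segments")


@dataclass
class NonlinearSummary:
    proportions: dict[str, float]  # per label, fraction of voiced frames
    jump_rate_per_min: float

    def as_dict(self) -> dict[str, float]:
        out = {f"prop_{lab}": self.proportions.get(lab, 0.0) for lab in PHENOMENON_LABELS}
        out["jump_rate_per_min"] = self.jump_rate_per_min
        return out


def phenomenon_proportions(ann: AnnotationTrack, contour: PitchContour) -> NonlinearSummary:
    """Fraction of voiced frames affected by each phenomenon, plus jump rate.

    A voiced frame counts as affected by label L iff its center time lies in
    any L segment (half-open [start, end), so splitting a segment into
    adjacent parts changes nothing).
    """
    voiced_t = contour.times[contour.voiced]
    if voiced_t.size == 0:
        raise ValueError("phenomenon_proportions: contour has no voiced frames")
    props = {}
    for lab in PHENOMENON_LABELS:
        covered = np.zeros(voiced_t.size, dtype=bool)
        for s, e, seg_lab in ann.segments:
            if seg_lab == lab:
                covered |= (voiced_t >= s) & (voiced_t < e)
        props[lab] = float(np.mean(covered))
    return NonlinearSummary(proportions=props, jump_rate_per_min=jump_rate(ann, contour))


def jump_rate(ann: AnnotationTrack, contour: PitchContour) -> float:
    """Frequency jumps per minute of voiced audio.

    A jump counts if it falls within half a frame step of a voiced frame
    center. Voiced duration = number of voiced frames x frame step.
    """
    voiced_t = contour.times[contour.voiced]
    if voiced_t.size == 0:
        raise ValueError("jump_rate: zero voiced duration")
    half = contour.step / 2
    n = sum(1 for tj in ann.jumps if np.any(np.abs(voiced_t - tj) <= half))
    voiced_s = voiced_t.size * contour.step
    return 60.0 * n / voiced_s


# ---------------------------------------------------------------------------
# zero-one-inflated beta


@dataclass
class ZOIBParams:
    zoi: float  # P(y in {0, 1})
    coi: float  # P(y = 1 | y in {0, 1}); nan when no inflated mass observed
    mu: float  # beta mean
    phi: float  # beta precision

    def validate(self) -> None:
        if not 0.0 <= self.zoi <= 1.0:
            raise ValueError(f"ZOIBParams.zoi: {self.zoi} not in [0, 1]")
        if not (np.isnan(self.coi) or 0.0 <= self.coi <= 1.0):
            raise ValueError(f"ZOIBParams.coi: {self.coi} not in [0, 1]")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"ZOIBParams.mu: {self.mu} not in (0, 1)")
        if self.phi <= 0:
            raise ValueError(f"ZOIBParams.phi: {self.phi} must be > 0")


def zoib_loglik(params: ZOIBParams, values: np.ndarray) -> float:
    """Sum of log-densities of ``values`` under the ZOIB distribution.

    Returns -inf if any value has zero density (e.g. a continuous value
    when zoi = 1). Values outside [0, 1] are an error.
    """
    params.validate()
    y = np.asarray(values, dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("zoib_loglik: values must lie in [0, 1]")
    coi = 0.0 if np.isnan(params.coi) else params.coi
    ll = 0.0
    is0, is1 = y == 0.0, y == 1.0
    mid = ~is0 & ~is1
    for mass, count in ((params.zoi * (1 - coi), is0.sum()), (params.zoi * coi, is1.sum())):
        if count:
            if mass == 0.0:
                return -np.inf
            ll += count * np.log(mass)
    if mid.any():
        if params.zoi == 1.0:
            return -np.inf
        a, b = params.mu * params.phi, (1 - params.mu) * params.phi
        ll += mid.sum() * np.log(1 - params.zoi) + float(
            np.sum(stats.beta.logpdf(y[mid], a, b))
        )
    return float(ll)


def _fit_beta_ml(y: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """ML fit of (mu, phi) for beta data in (0,1), on (logit mu, log phi)."""
    m, v = float(np.mean(y)), float(np.var(y))
    v = max(v, 1e-6)
    phi0 = max(m * (1 - m) / v - 1.0, 0.5)
    starts = [(special.logit(np.clip(m, 1e-3, 1 - 1e-3)), np.log(phi0))]
    rng = np.random.default_rng(seed)
    for _ in range(3):
        starts.append((starts[0][0] + rng.normal(0, 0.5), starts[0][1] + rng.normal(0, 0.7)))

    def nll(theta):
        mu = special.expit(theta[0])
        phi = np.exp(theta[1])
        return -np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))

    best = None
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return float(special.expit(best.x[0])), float(np.exp(best.x[1]))


def fit_zoib(
    values: np.ndarray,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> dict[str, tuple[ZOIBParams, float, bool]]:
    """Per-group maximum-likelihood ZOIB fit.

    The likelihood factorizes: the MLEs of (zoi, coi) are the closed-form
    frequencies zoi* = #(y in {0,1})/n and coi* = #(y=1)/#(y in {0,1});
    (mu, phi) are fit by multistart optimization on the link scale
    (logit/log) to the continuous values. coi is NaN when no inflated
    values are observed. Returns {group: (params, loglik, converged)}.
    """
    y = np.asarray(values, dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fit_zoib: values must lie in [0, 1]")
    if groups is None:
        groups = np.zeros(y.size, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        yg = y[groups == g]
        if yg.size < 10:
            raise ValueError(f"fit_zoib: group {g!r} has {yg.size} < 10 values")
        n_inf = int(np.sum((yg == 0) | (yg == 1)))
        n_one = int(np.sum(yg == 1))
        zoi = n_inf / yg.size
        coi = n_one / n_inf if n_inf else np.nan
        mid = yg[(yg > 0) & (yg < 1)]
        converged = True
        if mid.size >= 2:
            mu, phi = _fit_beta_ml(mid, seed=seed)
        elif mid.size == 1:
            mu, phi = float(mid[0]), 1.0
            converged = False
        else:
            mu, phi = 0.5, 1.0  # no continuous mass; beta part unidentified
            converged = False
        params = ZOIBParams(zoi=zoi, coi=coi, mu=mu, phi=phi)
        safe = ZOIBParams(zoi=zoi, coi=0.0 if np.isnan(coi) else coi, mu=mu, phi=phi)
        out[g] = (params, zoib_loglik(safe, yg), converged)
    return out


def simulate_zoib(params: ZOIBParams, n: int, seed: int = 0) -> np.ndarray:
    """Draw n values from the ZOIB distribution (deterministic given seed)."""
    if n <= 0:
        raise ValueError("simulate_zoib: n must be > 0")
    params.validate()
    coi = 0.0 if np.isnan(params.coi) else params.coi
    rng = np.random.default_rng(seed)
    inflated = rng.random(n) < params.zoi
    ones = rng.random(n) < coi
    a, b = params.mu * params.phi, (1 - params.mu) * params.phi
    cont = rng.beta(a, b, size=n)
    # guard against the rare exact 0/1 from the continuous draw
    eps = np.finfo(float).tiny
    cont = np.clip(cont, eps, 1 - 1e-16)
    y = np.where(inflated, ones.astype(float), cont)
    return y


# ---------------------------------------------------------------------------
# I/O: annotation CSV (start_s, end_s, label); jump events as zero-length rows


def write_annotation_csv(ann: AnnotationTrack, path) -> None:
    rows = [{"start_s": s, "end_s": e, "label": lab} for s, e, lab in ann.segments]
    rows += [{"start_s": tj, "end_s": tj, "label": "jump"} for tj in ann.jumps]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_annotation_csv(path) -> AnnotationTrack:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"annotation file is empty: {path}") from e
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col!r}: {path}")
    segments, jumps = [], []
    for _, row in df.iterrows():
        if row["label"] == "jump":
            jumps.append(float(row["start_s"]))
        else:
            segments.append((float(row["start_s"]), float(row["end_s"]), str(row["label"])))
    return AnnotationTrack(segments=segments, jumps=jumps)
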