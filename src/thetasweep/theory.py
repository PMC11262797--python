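"""Closed-form descriptors of the bump dynamics.

These are the projection-method results for the adaptive CANN: the
stationary bump amplitudes and their existence threshold, the intrinsic
traveling-wave speed under adaptation, and the sinusoidal oscillatory-
tracking solution (amplitude, offset, frequency) with the regime
classification that follows from it.

Derivation sketch.  A Gaussian bump ansatz

    U(x) = Au exp(-(x-z)^2 / 4 a^2),   r(x) = Ar exp(-(x-z)^2 / 2 a^2),
    V(x) = Av exp(-(x-z+d)^2 / 4 a^2)

is substituted into the dynamics and projected onto the two dominant motion
modes u0 = exp(-(x-z)^2/4a^2) (height) and u1 = (x-z) u0 (position).  The
modes themselves are derivation scaffolding only; this module implements the
resulting closed forms.  All constants below were re-derived from the
Gaussian integrals (Int exp(-x^2/2a^2) dx = sqrt(2 pi) a, etc.), carrying
the gain factor g through the algebra: g multiplies rho*J0 wherever the
recurrent drive enters, which matters because with the default parameters a
g-free threshold would (wrongly) predict no bump at all.

Accuracy caveat: the constant-shape ansatz treats the adaptation field as a
rigid Gaussian trailing the bump.  In the traveling-wave state the true
adaptation field is a one-sided exponential smear of length v*tau_v, so the
closed-form intrinsic speed runs ~25% above the simulated drift; the
oscillatory-tracking frequency is accurate to a few percent at the default
parameters.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "BumpSolution",
    "OscillationSolution",
    "critical_inhibition",
    "bump_fixed_point",
    "adapted_bump_solution",
    "oscillation_solution",
    "classify_regime",
]

_SQRT2PI = math.sqrt(2 * math.pi)


@dataclass(frozen=True)
class BumpSolution:
    """Stationary / traveling bump descriptors.

    Au, Ar, Av: amplitudes of the synaptic-input, firing-rate and adaptation
    bumps; d: spatial lag of the adaptation bump behind the activity bump
    (m); v_int: intrinsic traveling speed (m/s); kc: critical inhibition
    strength above which no bump exists; exists: whether the amplitude
    equations have a real solution.
    """

    Au: float
    Ar: float
    Av: float
    d: float
    v_int: float
    kc: float
    exists: bool


@dataclass(frozen=True)
class OscillationSolution:
    """Sinusoidal oscillatory-tracking descriptors.

    s(t) = z(t) - v_ext*t = c0 sin(omega t) + d0.  ``c0`` is the sweep
    amplitude (m), ``d0 = tau_v * v_ext`` the constant forward offset (m),
    ``omega`` the angular frequency in rad/ms (``freq_hz`` converts).
    ``oscillatory`` is False when the amplitude equation has no positive
    solution (smooth tracking); c0 is then 0.
    """

    Au: float
    Ar: float
    Av: float
    c0: float
    d0: float
    omega: float
    oscillatory: bool

    @property
    def freq_hz(self) -> float:
        return self.omega / (2 * math.pi) * 1000.0


def critical_inhibition(params: ModelParams) -> float:
    """Largest global inhibition that still admits a bump (no adaptation).

    kc = (g rho J0)^2 / (8 sqrt(2 pi) a rho): at k = kc the two roots of the
    amplitude quadratic merge; above it the network is silent.  Independent
    of tau, tau_v and m.
    """
    return (params.g * params.rho * params.J0) ** 2 / (
        8 * _SQRT2PI * params.a * params.rho
    )


def _amplitudes(params: ModelParams, load: float) -> tuple[float, float, bool]:
    """Stable root of the bump amplitude quadratic.

    ``load`` is the effective linear drain on Au: 1 for the plain bump,
    (1 + sqrt(m tau / tau_v)) when a traveling adaptation bump is present.
    Returns (Au, Ar, exists); the larger (+) root is the stable branch.
    """
    p = params
    A = 2 * math.sqrt(math.pi) * p.k * p.rho * p.a * load
    B = p.g * p.rho * p.J0
    disc = B * B - 4 * A * math.sqrt(2) * load
    if disc < 0:
        return 0.0, 0.0, False
    Au = (B + math.sqrt(disc)) / (2 * A)
    Ar = p.g * Au**2 / (1 + _SQRT2PI * p.k * p.rho * p.a * Au**2)
    return Au, Ar, True


def bump_fixed_point(params: ModelParams) -> BumpSolution:
    """Stationary bump amplitudes for the adaptation-free network (m = 0).

    Au = [g rho J0 + sqrt((g rho J0)^2 - 8 sqrt(2 pi) k rho a)]
         / (4 sqrt(pi) k rho a)

    together with Ar from the divisive normalization at that Au.  When
    k >= kc there is no real root and the silent state is reported via
    ``exists=False`` rather than an exception.
    """
    Au, Ar, exists = _amplitudes(params, 1.0)
    return BumpSolution(
        Au=Au, Ar=Ar, Av=0.0, d=0.0, v_int=0.0,
        kc=critical_inhibition(params), exists=exists,
    )


def adapted_bump_solution(params: ModelParams) -> BumpSolution:
    """Traveling (or static) bump under adaptation, no external input.

    For m <= tau/tau_v the adaptation is too weak to destabilize the bump:
    d = 0, v_int = 0.  Beyond the threshold, with lam = m tau_v / tau,

        d     = 2 a sqrt(1 - 1/sqrt(lam))
        v_int = (2 a / tau_v) sqrt(lam - sqrt(lam))      [m/ms internally]

    which together satisfy the center-motion consistency relation
    tau_v (1 - d^2/4a^2) v_int = d identically.  The amplitude quadratic
    acquires the drain factor (1 + sqrt(m tau/tau_v)).
    """
    p = params
    mu = math.sqrt(p.m * p.tau / p.tau_v)  # sqrt(m tau / tau_v)
    lam = p.m * p.tau_v / p.tau
    static = p.m <= p.tau / p.tau_v
    # at rest V = m U exactly, so the drain is (1 + m); in motion the
    # trailing adaptation bump unloads to (1 + sqrt(m tau/tau_v)).  The two
    # coincide at the mobility threshold m = tau/tau_v.
    Au, Ar, exists = _amplitudes(p, (1.0 + p.m) if static else (1.0 + mu))
    if static or not exists:
        d = 0.0
        v_ms = 0.0
        Av = p.m * Au
    else:
        q = 1.0 - 1.0 / math.sqrt(lam)  # d^2 / 4 a^2
        d = 2 * p.a * math.sqrt(q)
        v_ms = 2 * p.a / p.tau_v * math.sqrt(lam - math.sqrt(lam))
        # Av E = Au sqrt(m tau / tau_v) with E = exp(-d^2/8a^2)
        Av = Au * mu * math.exp(q / 2)
    return BumpSolution(
        Au=Au, Ar=Ar, Av=Av, d=d, v_int=v_ms * 1000.0,
        kc=critical_inhibition(p), exists=exists,
    )


def oscillation_solution(params: ModelParams) -> OscillationSolution:
    """Sinusoidal solution of the oscillatory tracking state (alpha > 0).

    In the inhibition-dominated regime the height equation linearizes to

        Au = (g J0 + 2 sqrt(pi) a k alpha) / (2 sqrt(pi) a k (1 + m))

    and the input restoring force sets the frequency omega^2 = alpha /
    (tau tau_v Au).  The adaptation amplitude Av = sqrt(m Au (tau Au +
    alpha tau_v) / tau_v) closes the sweep-amplitude equation

        c0^2 = Av^2 [8 a^2 ln(m Au / Av) - tau_v^2 v^2] / (2 alpha m Au),

    real only when the bracket is positive; otherwise the bump locks to the
    input (smooth tracking, c0 = 0).  The offset is d0 = tau_v * v.
    """
    p = params
    if p.alpha <= 0:
        raise ValueError("oscillation_solution requires alpha > 0")
    c = 2 * math.sqrt(math.pi) * p.a * p.k
    Au = (p.g * p.J0 + c * p.alpha) / (c * (1 + p.m))
    Ar = p.g * Au**2 / (1 + _SQRT2PI * p.k * p.rho * p.a * Au**2)
    omega = math.sqrt(p.alpha / (p.tau * p.tau_v * Au))
    v = p.v_ext_ms
    d0 = p.tau_v * v
    if p.m == 0:
        return OscillationSolution(Au, Ar, 0.0, 0.0, d0, omega, False)
    Av = math.sqrt(p.m * Au * (p.tau * Au + p.alpha * p.tau_v) / p.tau_v)
    bracket = 8 * p.a**2 * math.log(p.m * Au / Av) - (p.tau_v * v) ** 2
    if bracket <= 0:
        return OscillationSolution(Au, Ar, Av, 0.0, d0, omega, False)
    c0 = math.sqrt(Av**2 * bracket / (2 * p.alpha * p.m * Au))
    return OscillationSolution(Au, Ar, Av, c0, d0, omega, True)


def classify_regime(params: ModelParams) -> str:
    """Map parameters to one of the network's dynamical regimes.

    silent | static_bump | traveling_wave | smooth_tracking |
    oscillatory_tracking, by the decision tree: bump existence first, then
    the adaptation threshold (driven or not), then the sweep-amplitude sign.
    """
    if params.alpha == 0:
        sol = adapted_bump_solution(params)
        if not sol.exists:
            return "silent"
        return "traveling_wave" if params.m > params.tau / params.tau_v else "static_bump"
    osc = oscillation_solution(params)
    return "oscillatory_tracking" if osc.oscillatory else "smooth_tracking"
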