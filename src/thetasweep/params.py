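"""Model parameters and named presets.

All times are in milliseconds internally, all distances in meters.  The
external running speed ``v_ext`` is given in m/s at the user surface and
converted to m/ms where the integrator needs it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "PRESETS", "get_preset", "load_config"]


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the adaptive CANN dynamics.

    Parameters
    ----------
    tau:
        Time constant of the synaptic input U (ms).
    tau_v:
        Time constant of the adaptation current V (ms).  Adaptation must be
        slow compared to firing, ``tau_v > tau``.
    rho:
        Neuron density (neurons per meter on the 1D track; per square meter
        for 2D lattices).
    k:
        Global (divisive) inhibition strength.
    g:
        Gain factor of the firing-rate nonlinearity.
    J0:
        Peak recurrent connection strength.
    a:
        Range of the recurrent interaction (m); also the external input
        width ``sigma`` unless overridden.
    m:
        Firing-rate adaptation strength.
    alpha:
        External (location) input strength.
    sigma:
        External input width (m).  ``None`` means "equal to a".
    v_ext:
        Running speed of the simulated animal (m/s).
    dt:
        Euler time step (ms).
    T_total:
        Total simulated duration (s).
    """

    tau: float = 3.0
    tau_v: float = 144.0
    rho: float = 256.0 / 3.141592653589793
    k: float = 5.0
    g: float = 5.0
    J0: float = 0.2
    a: float = 0.4
    m: float = 0.0
    alpha: float = 0.0
    sigma: float | None = None
    v_ext: float = 1.5
    dt: float = 0.3
    T_total: float = 10.0

    def __post_init__(self) -> None:
        for name in ("tau", "tau_v", "rho", "a", "dt", "T_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k", "g", "J0", "m", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")
        if self.tau_v <= self.tau:
            raise ValueError("adaptation must be slow: tau_v > tau required")

    @property
    def sigma_eff(self) -> float:
        """Input width actually used (defaults to the interaction range)."""
        return self.a if self.sigma is None else self.sigma

    @property
    def v_ext_ms(self) -> float:
        """Running speed in m/ms."""
        return self.v_ext / 1000.0

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# Named parameter sets.  "linear_default" is the linear-track base set; the
# bimodal/unimodal presets differ only in the adaptation strength m, which
# controls how strongly backward sweeps are suppressed.
PRESETS: dict[str, ModelParams] = {
    "linear_default": ModelParams(alpha=0.19, m=3.02),
    "bimodal": ModelParams(alpha=0.19, m=3.02),
    "unimodal": ModelParams(alpha=0.19, m=3.125),
    "smooth_tracking": ModelParams(alpha=0.19, m=0.0),
    "traveling_wave": ModelParams(alpha=0.0, m=0.31),
    # Alternative time constants quoted alongside the main set.
    "linear_fast": ModelParams(tau=5.0, tau_v=100.0, alpha=0.19, m=3.02),
    # T-maze: 2D kernel; the location input there has Gaussian denominator
    # 2 a^2 rather than 4 sigma^2, i.e. sigma = a / sqrt(2).  Inhibition and
    # drive are rescaled for the 2D normalization so the network sits in the
    # oscillatory-tracking regime with sweeps long enough to enter the arms.
    "tmaze": ModelParams(
        a=0.3,
        J0=0.0125,
        k=0.02,
        alpha=2.0,
        m=3.7,
        T_total=4.2,
        rho=1.0 / 0.06**2,
        sigma=0.3 / 2**0.5,
    ),
}


def get_preset(name: str, **overrides: Any) -> ModelParams:
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return base.replace(**overrides) if overrides else base


def load_config(path: str | Path) -> ModelParams:
    """Read a YAML/JSON config with a ``model`` section into ModelParams.

    The file may specify ``preset`` (a name from :data:`PRESETS`) and/or a
    ``model`` mapping whose entries override individual fields.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    params = get_preset(data["preset"]) if "preset" in data else ModelParams()
    overrides = data.get("model", {})
    if not isinstance(overrides, dict):
        raise ValueError("'model' section must be a mapping")
    return params.replace(**overrides)
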