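"""Environment geometry: the 1D ring track and the 2D T-maze lattice.

The linear track is represented as a periodic ring so that a long run can
wrap without boundary artifacts; distances between neurons (and between the
decoded bump and the input) are always taken with the ring metric.  The
T-maze is a union of three rectangles covered by a square neuron lattice;
connectivity there uses plain Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronGrid",
    "TMazeGeometry",
    "build_linear_track",
    "build_tmaze",
    "tmaze_input_path",
]


@dataclass(frozen=True)
class NeuronGrid:
    """Neuron coordinates plus the metric used for connectivity.

    ``positions`` is (n,) for the 1D ring or (n, 2) for the T-maze.
    ``circumference`` is set only for ring topology.
    """

    positions: np.ndarray
    topology: str  # "ring" | "bounded-2d"
    circumference: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.topology == "ring":
            if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
                raise ValueError("ring positions must be 1D and strictly ordered")
            if self.circumference is None:
                raise ValueError("ring topology requires a circumference")
        elif self.topology == "bounded-2d":
            if pos.ndim != 2 or pos.shape[1] != 2:
                raise ValueError("2D grid positions must have shape (n, 2)")
            if len(np.unique(pos, axis=0)) != len(pos):
                raise ValueError("duplicate neuron coordinates")
        else:
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self, d: np.ndarray | float) -> np.ndarray | float:
        """Map a signed 1D displacement into (-L/2, L/2] on the ring."""
        if self.topology != "ring":
            return d
        L = self.circumference
        return (np.asarray(d) + L / 2) % L - L / 2

    def pairwise_distance(self) -> np.ndarray:
        """(n, n) distance matrix under the grid's metric."""
        pos = self.positions
        if self.topology == "ring":
            return np.abs(self.wrap(pos[:, None] - pos[None, :]))
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def distance_to(self, point: np.ndarray | float) -> np.ndarray:
        """Distance from every neuron to a point of the environment."""
        if self.topology == "ring":
            return np.abs(self.wrap(self.positions - point))
        return np.sqrt(((self.positions - np.asarray(point)) ** 2).sum(-1))


def build_linear_track(n_neurons: int = 512, rho: float = 256.0 / np.pi) -> NeuronGrid:
    """Uniform ring of ``n_neurons`` place cells at density ``rho`` per meter.

    The circumference is n/rho, so the defaults give 512 cells on a ring of
    2*pi meters with spacing 1/rho.
    """
    if n_neurons < 16:
        raise ValueError("need at least 16 neurons for a meaningful ring")
    spacing = 1.0 / rho
    positions = np.arange(n_neurons) * spacing
    return NeuronGrid(positions, "ring", circumference=n_neurons * spacing)


@dataclass(frozen=True)
class TMazeGeometry:
    """T-shaped arena: a vertical central arm and two horizontal side arms.

    The central arm runs along +y from (0, 0); the side arms extend along
    +/-x at the top.  The junction (choice point) is at (0, central_length).
    """

    central_width: float = 0.84
    central_length: float = 3.14
    arm_width: float = 0.84
    arm_length: float = 2.36
    grid_spacing: float = 0.06

    @property
    def junction(self) -> tuple[float, float]:
        return (0.0, self.central_length)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean point-in-T test for an (n, 2) array of coordinates."""
        x, y = np.asarray(xy)[..., 0], np.asarray(xy)[..., 1]
        in_central = (np.abs(x) <= self.central_width / 2) & (y >= 0) & (
            y <= self.central_length
        )
        top = self.central_length + self.arm_width
        in_bar = (
            (np.abs(x) <= self.arm_length + self.central_width / 2)
            & (y >= self.central_length)
            & (y <= top)
        )
        return in_central | in_bar


def build_tmaze(geometry: TMazeGeometry | None = None, a: float = 0.3) -> NeuronGrid:
    """Square lattice of place cells covering the T-shaped arena.

    ``a`` is the recurrent interaction range, used only for the resolution
    guard: the lattice must resolve the connectivity kernel.
    """
    geo = geometry or TMazeGeometry()
    h = geo.grid_spacing
    if h > a / 3:
        raise ValueError(
            f"grid_spacing {h} too coarse for interaction range {a}; need <= a/3"
        )
    xmax = geo.arm_length + geo.central_width / 2
    ymax = geo.central_length + geo.arm_width
    xs = np.arange(-xmax + h / 2, xmax, h)
    ys = np.arange(h / 2, ymax, h)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    return NeuronGrid(pts[geo.contains(pts)], "bounded-2d")


def tmaze_input_path(
    t_ms: float | np.ndarray,
    v_ext: float = 1.5,
    geometry: TMazeGeometry | None = None,
) -> np.ndarray:
    """Input-center trajectory on the central-arm midline.

    Starts at the arm base (0, 0) and moves toward the junction at ``v_ext``
    m/s, clamping there: the virtual animal does not commit to either arm.
    Returns coordinates with shape (..., 2).
    """
    geo = geometry or TMazeGeometry()
    y = np.minimum(np.asarray(t_ms, dtype=float) * v_ext / 1000.0, geo.central_length)
    return np.stack([np.zeros_like(y), y], axis=-1)
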