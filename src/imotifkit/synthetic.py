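"""Seeded generators for every input type the analysis consumes.

These emulate, with explicit statistical models, the data the downstream
stages expect: two-state van't Hoff melting ramps with direction-specific
midpoints (hysteresis), sigmoidal CD pH titrations, bisulfite-converted
clone sets with planted deletions, binomial dU-conversion mass peak lists,
and random genomes with planted repeats.  Every generator takes a SimConfig
and is byte-deterministic for a fixed seed; planting records are returned so
tests can use them as oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .massdist import DELTA_M_DU, PeakList
from .melting import MeltCurve
from .titration import TitrationSeries
from .bisulfite import ReferenceRegion

__all__ = [
    "GAS_CONSTANT_KCAL",
    "SimConfig",
    "BisulfiteRates",
    "CloneSet",
    "GenomeSim",
    "gen_melt_curve",
    "gen_titration",
    "gen_clone_set",
    "gen_peak_list",
    "gen_genome",
    "state_map_for_region",
]

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)
_KELVIN = 273.15

# structural states a cytosine can occupy, ordered by bisulfite reactivity
STATES = ("C_PLUS_SS", "CC_PLUS", "C_SS", "CG_DUPLEX")


@dataclass(frozen=True)
class SimConfig:
    """Simulation plumbing: seed, noise level, replicate count.

    ``noise_sd`` is expressed as a fraction of the signal amplitude.  The
    same seed and parameters always give byte-identical output.
    """

    seed: int = 0
    noise_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class BisulfiteRates:
    """Per-state probabilities that a cytosine is converted to uracil.

    The defaults follow the frontier-orbital reactivity ordering of cytosine
    electrophiles toward the bisulfite anion, dC+ > C:C+ >> C:G > dC: a
    protonated single-stranded cytosine is most reactive, the hemiprotonated
    C:C+ pair of an i-motif nearly as reactive, and Watson-Crick-paired or
    unprotonated cytosines nearly inert.  The C:C+ default is scaled to
    reproduce the conversion level observed at a long genomic repeat.
    """

    p_cc_plus: float = 0.35     # C in a C:C+ i-motif pair
    p_c_plus_ss: float = 0.45   # protonated single-stranded C
    p_cg_duplex: float = 0.01   # Watson-Crick paired C
    p_c_ss: float = 0.05        # unprotonated single-stranded C

    def __post_init__(self):
        for name in ("p_cc_plus", "p_c_plus_ss", "p_cg_duplex", "p_c_ss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    def for_state(self, state: str) -> float:
        try:
            return {"CC_PLUS": self.p_cc_plus,
                    "C_PLUS_SS": self.p_c_plus_ss,
                    "CG_DUPLEX": self.p_cg_duplex,
                    "C_SS": self.p_c_ss}[state]
        except KeyError:
            raise ValueError(f"unknown structural state {state!r}") from None


def _as_baseline(b):
    if callable(b):
        return b
    intercept, slope = b
    return lambda t: intercept + slope * np.asarray(t, dtype=float)


def gen_melt_curve(tm: float, direction: str = "melt", dh: float = -40.0,
                   baselines=((1.0, 0.0), (0.7, 0.0)),
                   grid=None, cfg: SimConfig = SimConfig(),
                   replicate_id: int = 0, label: str = "",
                   buffer=None) -> MeltCurve:
    """Two-state van't Hoff melting/annealing curve with optional noise.

    A(T) = (1-alpha) * base_folded(T) + alpha * base_unfolded(T), where the
    fraction unfolded is the linearised (symmetric-in-T) van't Hoff
    logistic alpha(T) = 1 / (1 + exp[(dh / (R Tm_K^2)) (T - Tm)]) with
    dh < 0 (folding exotherm convention), so alpha -> 1 at high temperature,
    alpha(Tm) = 1/2, and the steepest slope sits exactly at Tm with the
    van't Hoff magnitude |dh| / (4 R Tm_K^2).  ``baselines`` are two linear
    functions of T given as
    (intercept, slope) pairs or callables, folded first; the default folded
    baseline lies above the unfolded one because i-motif unfolding is
    hypochromic at 295 nm.  Hysteresis is emulated by generating annealing
    curves with their own (lower) midpoint.  Gaussian noise has sd
    cfg.noise_sd times the baseline amplitude.
    """
    if dh >= 0:
        raise ValueError("dh must be negative (folding exotherm convention)")
    if grid is None:
        grid = np.arange(4.0, 96.0, 1.0)
        if direction == "anneal":
            grid = grid[::-1]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty temperature grid")
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("grid must be strictly monotone")
    if not (grid.min() <= tm <= grid.max()):
        warnings.warn(f"midpoint {tm} outside grid span "
                      f"[{grid.min()}, {grid.max()}]", stacklevel=2)

    base_f = _as_baseline(baselines[0])
    base_u = _as_baseline(baselines[1])
    tm_k = tm + _KELVIN
    slope = dh / (GAS_CONSTANT_KCAL * tm_k**2)
    alpha = 1.0 / (1.0 + np.exp(slope * (grid - tm)))
    signal = (1.0 - alpha) * base_f(grid) + alpha * base_u(grid)
    if cfg.noise_sd > 0:
        amp = float(np.mean(np.abs(base_f(grid) - base_u(grid))))
        signal = signal + cfg.rng(replicate_id).normal(
            0.0, cfg.noise_sd * amp, size=grid.size)
    return MeltCurve(temperatures=grid, signal=signal, direction=direction,
                     replicate_id=replicate_id, label=label, buffer=buffer)


def gen_titration(ph_t: float, hill: float = 1.5, theta_folded: float = 6.0,
                  theta_unfolded: float = 0.5, grid=None,
                  cfg: SimConfig = SimConfig(), replicate_id: int = 0,
                  label: str = "") -> TitrationSeries:
    """Sigmoidal ellipticity-at-288nm titration with optional noise.

    theta(pH) = theta_u + (theta_f - theta_u) / (1 + 10^(hill (pH - ph_t))),
    so the folded baseline is attained at low pH (i-motif folded when
    acidic).  The default grid is pH 5.0 to 8.0 in 0.25 steps.  Gaussian
    noise has sd cfg.noise_sd times |theta_f - theta_u|.
    """
    if grid is None:
        grid = np.arange(5.0, 8.0 + 1e-9, 0.25)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 4.0 or grid.max() > 9.0:
        raise ValueError("pH grid must lie within [4, 9]")
    if theta_folded == theta_unfolded:
        raise ValueError("degenerate amplitude: theta_folded == theta_unfolded")
    theta = theta_unfolded + (theta_folded - theta_unfolded) / (
        1.0 + 10.0 ** (hill * (grid - ph_t)))
    if cfg.noise_sd > 0:
        amp = abs(theta_folded - theta_unfolded)
        theta = theta + cfg.rng(replicate_id).normal(
            0.0, cfg.noise_sd * amp, size=grid.size)
    return TitrationSeries(ph=grid, ellipticity=theta,
                           replicate_id=replicate_id, label=label)


def state_map_for_region(region: ReferenceRegion,
                         element_state: str = "CC_PLUS",
                         background_state: str = "CG_DUPLEX") -> dict[int, str]:
    """Assign a structural state to every C position of a reference region.

    Cytosines inside annotated repeat elements get ``element_state`` (folded
    i-motif by default); all other cytosines get ``background_state``
    (duplex by default).
    """
    for st in (element_state, background_state):
        if st not in STATES:
            raise ValueError(f"unknown structural state {st!r}")
    in_element = set()
    for el in region.elements:
        in_element.update(range(el.start, el.end))
    return {i: (element_state if i in in_element else background_state)
            for i, b in enumerate(region.sequence) if b == "C"}


@dataclass(frozen=True)
class CloneSet:
    """Generated clones plus the planting record used as a test oracle."""

    clones: list[tuple[str, str]]                 # (clone_id, sequence)
    planted_deletions: dict[int, list[tuple[int, int]]]  # clone idx -> intervals
    converted_positions: list[list[int]]          # ref C positions per clone


def gen_clone_set(region: ReferenceRegion, n_clones: int,
                  rates: BisulfiteRates | None = None,
                  state_map: dict[int, str] | None = None,
                  deletions: list[tuple[int, tuple[int, int]]] = (),
                  cfg: SimConfig = SimConfig()) -> CloneSet:
    """Simulate bisulfite-converted clones of a region with planted deletions.

    Each clone is the reference with (a) its planted deletion intervals
    excised and (b) every surviving C independently converted to T with the
    probability of its structural state.  ``deletions`` is a list of
    (clone_index, (ref_start, ref_end)).  Non-C bases are untouched.
    """
    rates = rates or BisulfiteRates()
    state_map = state_map if state_map is not None else state_map_for_region(region)
    seq = region.sequence
    c_positions = [i for i, b in enumerate(seq) if b == "C"]
    missing = [i for i in c_positions if i not in state_map]
    if missing:
        raise ValueError(f"state_map does not cover C positions {missing[:5]}...")

    per_clone: dict[int, list[tuple[int, int]]] = {}
    for idx, (start, end) in deletions:
        if not 0 <= idx < n_clones:
            raise ValueError(f"clone index {idx} out of range")
        if not 0 <= start < end <= len(seq):
            raise ValueError(f"deletion [{start}, {end}) outside region")
        per_clone.setdefault(idx, []).append((start, end))
    for idx, ivals in per_clone.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping planted deletions in clone {idx}")

    p_by_pos = {i: rates.for_state(state_map[i]) for i in c_positions}
    clones = []
    converted_record = []
    rng = cfg.rng()
    for idx in range(n_clones):
        deleted = set()
        for s, e in per_clone.get(idx, []):
            deleted.update(range(s, e))
        bases = []
        converted = []
        for i, b in enumerate(seq):
            if i in deleted:
                continue
            if b == "C" and rng.random() < p_by_pos[i]:
                bases.append("T")
                converted.append(i)
            else:
                bases.append(b)
        clones.append((f"clone{idx:03d}", "".join(bases)))
        converted_record.append(converted)
    return CloneSet(clones=clones, planted_deletions=per_clone,
                    converted_positions=converted_record)


def gen_peak_list(ref_mass: float, n_cytosines: int, p_convert: float,
                  n_molecules: int, fragment_fraction: float = 0.0,
                  cfg: SimConfig = SimConfig(),
                  delta_m: float = DELTA_M_DU) -> PeakList:
    """Binomial dU-conversion peak list for a deconvoluted mass spectrum.

    Each of ``n_molecules`` molecules converts k ~ Binomial(n_cytosines,
    p_convert) cytosines; species k appears at ref_mass + k * delta_m with
    abundance equal to its molecule count.  When ``fragment_fraction`` > 0,
    low-mass breakage fragments are added so they carry exactly that share
    of the total abundance (three peaks at 0.35, 0.55 and 0.8 times the
    reference mass).
    """
    if not 0.0 <= p_convert <= 1.0:
        raise ValueError("p_convert must be a probability")
    if n_cytosines < 1:
        raise ValueError("n_cytosines must be >= 1")
    if not 0.0 <= fragment_fraction < 1.0:
        raise ValueError("fragment_fraction must lie in [0, 1)")
    rng = cfg.rng()
    ks = rng.binomial(n_cytosines, p_convert, size=n_molecules)
    counts = np.bincount(ks, minlength=n_cytosines + 1)
    masses = [ref_mass + k * delta_m for k in range(n_cytosines + 1)
              if counts[k] > 0]
    abundances = [float(counts[k]) for k in range(n_cytosines + 1)
                  if counts[k] > 0]
    if fragment_fraction > 0:
        frag_total = fragment_fraction / (1.0 - fragment_fraction) * n_molecules
        for frac_mass, share in ((0.35, 0.5), (0.55, 0.3), (0.8, 0.2)):
            masses.append(ref_mass * frac_mass)
            abundances.append(frag_total * share)
    return PeakList(masses=np.asarray(masses),
                    abundances=np.asarray(abundances))


@dataclass(frozen=True)
class GenomeSim:
    """A simulated genome and the coordinates of its planted repeats."""

    sequence: str
    planted: list[tuple[int, str, int]]  # (position, unit, n)


def gen_genome(length: int, planted: list[tuple[int, str, int]] = (),
               cfg: SimConfig = SimConfig()) -> GenomeSim:
    """Uniform-random genome with exact planted repeat elements.

    ``planted`` entries are (position, unit, n); a GGGA unit plants the
    element on the reverse strand.  Planted intervals must not overlap.
    """
    ivals = sorted((pos, pos + 4 * n, unit, n) for pos, unit, n in planted)
    for (s1, e1, *_), (s2, e2, *_) in zip(ivals, ivals[1:]):
        if s2 < e1:
            raise ValueError("planted elements overlap")
    for s, e, *_ in ivals:
        if s < 0 or e > length:
            raise ValueError("planted element outside genome")
    rng = cfg.rng()
    seq = rng.choice(np.array(list("ACGT")), size=length)
    for s, e, unit, n in ivals:
        seq[s:e] = list(unit * n)
    return GenomeSim(sequence="".join(seq),
                     planted=[(p, u, n) for p, u, n in planted])
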