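"""Model parameters, reactor geometry, and the operon annotation.

Everything downstream of this module shares the conventions fixed here:

* operon coordinates are 1-based, closed intervals on the transcript,
  position 0 being the reserved "not yet initiated" state of a polymerase;
* the internal time unit is the second — flow rates (mL min^-1) and the
  dilution rate (h^-1) are converted once, at load time;
* gene regions are ordered 5'->3' and must not overlap.

The packaged default annotation describes the E. coli trp operon
(trpL leader followed by trpE, trpD, trpC, trpB, trpA) on a 6726 nt
transcript, with per-gene translations-per-mRNA quotas of 4, 4, 5, 10
and 10 for the structural genes.  Gene boundaries follow the K-12 CDS
lengths, shifted so trpA ends on the last transcript nucleotide; they
only shift protein appearance times by seconds and can be replaced by
pointing a config file at a different annotation table.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "ConfigError",
    "AnnotationError",
    "SimulationParameters",
    "ReactorConfig",
    "GeneRegion",
    "OperonDefinition",
    "default_trp_operon",
    "read_operon_table",
    "write_operon_table",
    "load_config",
    "write_config",
]


class ConfigError(ValueError):
    """A parameter failed validation; the message names the field."""


class AnnotationError(ValueError):
    """The operon annotation violates the coordinate conventions."""


@dataclass(frozen=True)
class SimulationParameters:
    """Single-cell lattice parameters.

    Defaults are the literature-documented values used throughout:
    all three species elongate at 21 nt/s, minimum spacings are 100 nt,
    and the induction window opens 30 s after PFR entry and closes at
    125 s (the PFR residence time).

    ``dt_step`` defaults to one nucleotide per elongation step
    (1 / max velocity), which makes agent movement exact integer hops.
    """

    velo_rnap: float = 21.0      # nt s^-1
    velo_ribosome: float = 21.0  # nt s^-1
    velo_rnase: float = 21.0     # nt s^-1
    delta_x: int = 100           # min RNAP-RNAP spacing, nt
    delta_y: int = 100           # min ribosome-ribosome spacing, nt
    delta_z: int = 100           # min RNase-to-ribosome spacing, nt
    t_ind: tuple[float, float] = (30.0, 125.0)  # s after PFR entry
    dt_step: float | None = None  # s; None -> 1/max(velocity)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("velo_rnap", "velo_ribosome", "velo_rnase"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("delta_x", "delta_y", "delta_z"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1 nt")
        start, end = self.t_ind
        if not start < end:
            # a zero-width window [a, a] is permitted (single initiation)
            if start != end:
                raise ConfigError("t_ind start must be <= end")
        if start < 0:
            raise ConfigError("t_ind start must be >= 0")
        if self.dt_step is not None and not self.dt_step > 0:
            raise ConfigError("dt_step must be > 0")

    @property
    def dt(self) -> float:
        """Effective integration step in seconds."""
        if self.dt_step is not None:
            return self.dt_step
        return 1.0 / max(self.velo_rnap, self.velo_ribosome, self.velo_rnase)


@dataclass(frozen=True)
class ReactorConfig:
    """STR-PFR geometry, flows and population-balance constants.

    ``tau_pfr`` and ``tau_str`` are the residence times the simulator
    actually uses; their defaults are the experimentally reported 125 s
    and 6.2 min rather than the values recomputed from volumes and flow
    (126.7 s / 6.22 min), because the PFR sampling ports and the end of
    the induction window are tied to the reported numbers.
    """

    v_str: float = 1120.0        # mL
    v_pfr: float = 380.0         # mL
    q_pfr: float = 180.0         # mL min^-1 through the PFR loop
    q_feed: float = 5.0          # mL min^-1 feed/harvest
    dilution_rate: float = 0.2   # h^-1
    n0: int = 10_000             # initial cell count in the STR
    tau_pfr: float = 125.0       # s, deterministic PFR transit
    tau_str: float = 372.0       # s, nominal STR residence (6.2 min)

    def __post_init__(self) -> None:
        for name in ("v_str", "v_pfr"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0 mL")
        for name in ("q_pfr", "q_feed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 mL/min")
        if self.dilution_rate < 0:
            raise ConfigError("dilution_rate must be >= 0 h^-1")
        if self.n0 < 0:
            raise ConfigError("n0 must be >= 0 cells")
        if not self.tau_pfr > 0:
            raise ConfigError("tau_pfr must be > 0 s")
        if not self.tau_str > 0:
            raise ConfigError("tau_str must be > 0 s")

    # -- derived quantities (all in seconds / per second) -------------

    @property
    def tau_pfr_from_flows(self) -> float:
        """v_pfr / q_pfr in seconds (126.7 s with defaults)."""
        return self.v_pfr / self.q_pfr * 60.0

    @property
    def tau_str_from_flows(self) -> float:
        """v_str / q_pfr in seconds (373.3 s with defaults)."""
        return self.v_str / self.q_pfr * 60.0

    @property
    def pfr_entry_rate_per_cell(self) -> float:
        """q_pfr / v_str in s^-1: per-STR-cell rate of entering the PFR."""
        return self.q_pfr / self.v_str / 60.0

    @property
    def washout_rate_per_cell(self) -> float:
        """q_feed / v_str in s^-1: per-STR-cell harvest rate."""
        return self.q_feed / self.v_str / 60.0

    @property
    def division_rate(self) -> float:
        """n0 * D in s^-1: constant whole-population birth rate."""
        return self.n0 * self.dilution_rate / 3600.0

    @property
    def volumetric_fractions(self) -> tuple[float, float]:
        """(STR, PFR) liquid-volume fractions of the total system."""
        total = self.v_str + self.v_pfr
        return self.v_str / total, self.v_pfr / total


@dataclass(frozen=True)
class GeneRegion:
    """One gene on the operon transcript.

    ``n_tl_max`` is the translations-per-mRNA quota: the number of
    ribosome initiations each transcript receives on this gene before
    the degradation machinery is allowed to proceed through it.  A
    quota of 0 (the untranslated leader) leaves the region free for
    immediate degradation.
    """

    name: str
    c_start: int  # first coding nucleotide, 1-based
    c_end: int    # last nucleotide of the stop codon, 1-based
    n_tl_max: int

    def __post_init__(self) -> None:
        if self.c_start < 1:
            raise AnnotationError(f"{self.name}: c_start must be >= 1")
        if not self.c_start < self.c_end:
            raise AnnotationError(f"{self.name}: c_start must be < c_end")
        if self.n_tl_max < 0:
            raise AnnotationError(f"{self.name}: n_tl_max must be >= 0")


@dataclass(frozen=True)
class OperonDefinition:
    """Ordered, non-overlapping gene regions on one transcript."""

    length: int
    genes: tuple[GeneRegion, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError("operon length must be >= 1 nt")
        prev_end = 0
        for g in self.genes:
            if g.c_start <= prev_end:
                raise AnnotationError(
                    f"{g.name}: regions must be ordered 5'->3' and non-overlapping"
                )
            if g.c_end > self.length:
                raise AnnotationError(
                    f"{g.name}: c_end {g.c_end} exceeds operon length {self.length}"
                )
            prev_end = g.c_end

    def __iter__(self) -> Iterator[GeneRegion]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def __getitem__(self, name: str) -> GeneRegion:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def translated(self) -> tuple[GeneRegion, ...]:
        """Genes with a nonzero translation quota (protein accounting)."""
        return tuple(g for g in self.genes if g.n_tl_max > 0)


# ---------------------------------------------------------------------------
# annotation table I/O
# ---------------------------------------------------------------------------

_OPERON_COLUMNS = ("name", "c_start", "c_end", "n_tl_max")


def read_operon_table(path: Path | str, length: int) -> OperonDefinition:
    """Read a tab-separated gene table (header required) into an operon."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise AnnotationError(f"{path}: empty annotation file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _OPERON_COLUMNS:
        expected = "\t".join(_OPERON_COLUMNS)
        raise AnnotationError(f"{path}: header must be {expected!r}")
    genes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        name, c_start, c_end, n_tl = line.split("\t")
        genes.append(GeneRegion(name, int(c_start), int(c_end), int(n_tl)))
    return OperonDefinition(length=length, genes=tuple(genes))


def write_operon_table(operon: OperonDefinition, path: Path | str) -> None:
    rows = ["\t".join(_OPERON_COLUMNS)]
    rows += [
        f"{g.name}\t{g.c_start}\t{g.c_end}\t{g.n_tl_max}" for g in operon.genes
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def default_trp_operon() -> OperonDefinition:
    """The packaged trp operon annotation (6726 nt, trpL-EDCBA).

    Quotas per structural gene: trpE 4, trpD 4, trpC 5, trpB 10 and
    trpA 10 (trpA adopted from trpB, the two forming the 2+2 tryptophan
    synthase complex); the trpL leader carries quota 0 and is excluded
    from protein accounting.
    """
    ref = resources.files("strpfr").joinpath("data/trp_operon.tsv")
    with resources.as_file(ref) as path:
        return read_operon_table(path, length=6726)


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------

_SIM_FIELDS = {
    "velo_rnap": float, "velo_ribosome": float, "velo_rnase": float,
    "delta_x": int, "delta_y": int, "delta_z": int,
    "dt_step": float, "rng_seed": int,
}
_REACTOR_FIELDS = {
    "v_str": float, "v_pfr": float, "q_pfr": float, "q_feed": float,
    "dilution_rate": float, "n0": int, "tau_pfr": float, "tau_str": float,
}


def load_config(
    path: Path | str,
) -> tuple[SimulationParameters, ReactorConfig, OperonDefinition]:
    """Load a TOML config; omitted fields take the packaged defaults.

    Sections: ``[simulation]``, ``[reactor]`` and ``[operon]`` (with an
    optional ``annotation`` path, resolved relative to the config file,
    and an optional ``length``).  An empty file reproduces the full
    default parameter set.
    """
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    sim_kw: dict = {}
    for key, value in raw.get("simulation", {}).items():
        if key == "t_ind":
            sim_kw["t_ind"] = (float(value[0]), float(value[1]))
        elif key in _SIM_FIELDS:
            sim_kw[key] = _SIM_FIELDS[key](value)
        else:
            raise ConfigError(f"unknown [simulation] field: {key}")
    params = SimulationParameters(**sim_kw)

    reactor_kw: dict = {}
    for key, value in raw.get("reactor", {}).items():
        if key not in _REACTOR_FIELDS:
            raise ConfigError(f"unknown [reactor] field: {key}")
        reactor_kw[key] = _REACTOR_FIELDS[key](value)
    reactor = ReactorConfig(**reactor_kw)

    op_raw = raw.get("operon", {})
    length = int(op_raw.get("length", 6726))
    if "annotation" in op_raw:
        ann = (path.parent / op_raw["annotation"]).resolve()
        operon = read_operon_table(ann, length=length)
    else:
        operon = default_trp_operon()
        if length != operon.length:
            operon = replace(operon, length=length)
    return params, reactor, operon


def write_config(
    params: SimulationParameters,
    reactor: ReactorConfig,
    operon: OperonDefinition,
    path: Path | str,
) -> None:
    """Write a TOML config plus a sibling annotation table.

    ``load_config(write_config(...))`` round-trips field for field.
    """
    path = Path(path)
    ann_path = path.with_suffix(".operon.tsv")
    write_operon_table(operon, ann_path)

    def fmt(value) -> str:
        if isinstance(value, bool):
            raise ConfigError("boolean config values are not used")
        if isinstance(value, (int, float)):
            return repr(value)
        return f'"{value}"'

    lines = ["[simulation]"]
    for key in _SIM_FIELDS:
        value = getattr(params, key)
        if value is None:
            continue
        lines.append(f"{key} = {fmt(value)}")
    lines.append(f"t_ind = [{params.t_ind[0]!r}, {params.t_ind[1]!r}]")
    lines.append("")
    lines.append("[reactor]")
    for key in _REACTOR_FIELDS:
        lines.append(f"{key} = {fmt(getattr(reactor, key))}")
    lines.append("")
    lines.append("[operon]")
    lines.append(f"length = {operon.length}")
    lines.append(f'annotation = "{ann_path.name}"')
    path.write_text("\n".join(lines) + "\n")
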