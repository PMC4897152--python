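"""Run configuration: flat key-value files, defaults, experiment suites.

A run is described by a flat plain-text file of ``key: value`` lines
(``#`` starts a comment).  An empty file reproduces the base case of the
study: lambda = 0.5, l = 2, d = 3, Re = 400, p0 = 0.1, p1 = 0.2 p0,
60 x 60 grid, dt = 0.01, t_end = 10, with body acceleration a0 = p0 in
phase with the pressure pulse.

Derived keys: ``p1`` may be given directly or via ``p1_ratio`` (p1 =
p1_ratio * p0); ``omega`` may be given directly or via the nondimensional
pulse frequency ``f`` (omega = 2 pi f); ``grid: 60x60`` sets M and N at
once; ``a0`` defaults to p0 and ``omega_body`` to omega.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .forcing import DEFAULT_OMEGA, BodyAcceleration, PressureForcing
from .geometry import StenosisGeometry
from .solver import Grid, RunResult, SolverConfig, simulate

__all__ = ["RunConfig", "load_config", "parse_config", "experiment_suite", "run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of one simulation run."""

    # geometry
    lambda_: float = 0.5
    l: float = 2.0
    d: float = 3.0
    domain_length: float = 10.0
    # forcing
    re: float = 400.0
    p0: float = 0.1
    p1: float = 0.02
    omega: float = DEFAULT_OMEGA
    a0: float = 0.1
    phi: float = 0.0
    omega_body: float = DEFAULT_OMEGA
    # discretization
    M: int = 60
    N: int = 60
    dt: float = 0.01
    t_end: float = 10.0
    snapshot_interval: float = 1.0
    # reporting / numerics
    mu: float = 1.0
    safety_factor: float = 0.9
    advection: str = "upwind"
    junction_rounding: float = 0.4
    label: str = "run"

    def build(
        self,
    ) -> tuple[StenosisGeometry, Grid, PressureForcing, BodyAcceleration, SolverConfig]:
        """Construct (and thereby validate) the domain objects of this run."""
        geom = StenosisGeometry(
            lambda_=self.lambda_, l=self.l, d=self.d, domain_length=self.domain_length
        )
        grid = Grid(M=self.M, N=self.N, domain_length=self.domain_length, dt=self.dt)
        pressure = PressureForcing(p0=self.p0, p1=self.p1, omega=self.omega)
        body = BodyAcceleration(a0=self.a0, phi=self.phi, omega=self.omega_body)
        solver = SolverConfig(
            re=self.re,
            safety_factor=self.safety_factor,
            advection=self.advection,
            junction_rounding=self.junction_rounding,
        )
        return geom, grid, pressure, body, solver

    def without_body_acceleration(self) -> "RunConfig":
        return replace(self, a0=0.0, label=self.label + "-noacc")

    def as_dict(self) -> dict:
        return asdict(self)


#: keys accepted in a config file that are not RunConfig fields verbatim
_DERIVED_KEYS = {"p1_ratio", "f", "grid", "lambda"}
_INT_KEYS = {"M", "N"}
_STR_KEYS = {"label", "grid", "advection"}


def _coerce(key: str, raw: str):
    if key in _STR_KEYS:
        return raw
    try:
        return int(raw) if key in _INT_KEYS else float(raw)
    except ValueError as exc:
        raise ValueError(f"{key}: cannot parse value {raw!r}") from exc


def parse_config(text: str) -> RunConfig:
    """Parse flat ``key: value`` text into a validated :class:`RunConfig`."""
    known = set(RunConfig.__dataclass_fields__) | _DERIVED_KEYS
    raw: dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        sep = ":" if ":" in body else "="
        if sep not in body:
            raise ValueError(f"line {lineno}: expected 'key: value', got {body!r}")
        key, _, value = body.partition(sep)
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        if key in raw:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        raw[key] = _coerce(key, value)

    if "lambda" in raw:
        raw["lambda_"] = raw.pop("lambda")
    if "grid" in raw:
        spec = str(raw.pop("grid")).lower()
        try:
            m_str, n_str = spec.split("x")
            raw["M"], raw["N"] = int(m_str), int(n_str)
        except ValueError as exc:
            raise ValueError(f"grid: expected 'MxN', got {spec!r}") from exc

    defaults = RunConfig()
    p0 = float(raw.get("p0", defaults.p0))
    if "p1" in raw and "p1_ratio" in raw:
        raise ValueError("give either p1 or p1_ratio, not both")
    if "p1" not in raw and ("p1_ratio" in raw or "p0" in raw):
        ratio = float(raw.pop("p1_ratio", 0.2))
        raw["p1"] = ratio * p0
    if "f" in raw:
        if "omega" in raw:
            raise ValueError("give either omega or f, not both")
        raw["omega"] = 2.0 * math.pi * float(raw.pop("f"))
    omega = float(raw.get("omega", defaults.omega))
    raw.setdefault("omega_body", omega)
    raw.setdefault("a0", p0)

    cfg = RunConfig(**raw)  # type: ignore[arg-type]
    cfg.build()  # validate parameter ranges eagerly
    return cfg


def load_config(path) -> RunConfig:
    """Read and validate a run-configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    return parse_config(p.read_text())


def run_config(cfg: RunConfig, snapshot_interval: float | None = None) -> RunResult:
    """Execute a configured run and attach its manifest metadata."""
    geom, grid, pressure, body, solver = cfg.build()
    interval = snapshot_interval if snapshot_interval is not None else cfg.snapshot_interval
    result = simulate(geom, grid, pressure, body, solver, cfg.t_end, interval)
    result.manifest = _manifest_dict(cfg)
    return result


def _manifest_dict(cfg: RunConfig) -> dict:
    from . import __version__

    manifest = {"stenoflow_version": __version__, "deterministic": True}
    manifest.update(cfg.as_dict())
    return manifest


# ---------------------------------------------------------------------- #
# figure-reproduction experiment suites
# ---------------------------------------------------------------------- #
def experiment_suite(name: str) -> list[RunConfig]:
    """Configs reproducing the panels of one of the study's result figures.

    Supported names: fig3/fig11 (body acceleration on vs off at Re = 400),
    fig4/fig9/fig10 (Re sweep 400/600/800), fig6/fig7 (Re in {400, 800} x
    body acceleration on/off), fig8 (Re = 400 on/off), fig12 (straight
    tube, no constriction).
    """
    base = RunConfig()
    re_sweep = (400.0, 600.0, 800.0)

    def with_re(re: float, label: str) -> RunConfig:
        return replace(base, re=re, label=label)

    suites: dict[str, list[RunConfig]] = {
        "fig3": [
            replace(base, label="fig3-acc"),
            replace(base, a0=0.0, label="fig3-noacc"),
        ],
        "fig4": [with_re(re, f"fig4-re{int(re)}") for re in re_sweep],
        "fig6": [
            replace(base, re=re, a0=a0, label=f"fig6-re{int(re)}-{'acc' if a0 else 'noacc'}")
            for re in (400.0, 800.0)
            for a0 in (base.a0, 0.0)
        ],
        "fig8": [
            replace(base, label="fig8-acc"),
            replace(base, a0=0.0, label="fig8-noacc"),
        ],
        "fig9": [
            replace(base, re=re, a0=a0, label=f"fig9-re{int(re)}-{'acc' if a0 else 'noacc'}")
            for a0 in (base.a0, 0.0)
            for re in re_sweep
        ],
        "fig11": [
            replace(base, label="fig11-acc"),
            replace(base, a0=0.0, label="fig11-noacc"),
        ],
        "fig12": [replace(base, lambda_=0.0, label="fig12-straight")],
    }
    suites["fig7"] = [replace(c, label=c.label.replace("fig6", "fig7")) for c in suites["fig6"]]
    suites["fig10"] = [replace(c, label=c.label.replace("fig9", "fig10")) for c in suites["fig9"]]
    try:
        return suites[name]
    except KeyError:
        raise ValueError(
            f"unknown experiment suite {name!r}; known: {sorted(suites)}"
        ) from None
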