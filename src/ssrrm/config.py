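"""Pipeline configuration: defaults, validation, normalisation.

A run is configured either by input file paths (pedigree/genotypes/daily
phenotypes/covariates) or by a simulation block — exactly one of the two.
Defaults follow the selected evaluation settings: blending
(alpha, beta, tau, omega) = (0.95, 0.05, 1, 1), Legendre orders
(p, q, n) = (2, 1, 1), minimum 34 retained days after a 7-day adaptation
cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np

from .relmat import HBlendParams
from .simdata import SimConfig

__all__ = ["PipelineConfig", "validate_config"]

DEFAULT_GRID = [(p, q, n) for p in (1, 2) for q in (1, 2) for n in (1, 2)]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    sim: SimConfig | None = None
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    covariates_path: str | None = None
    grid: list = field(default_factory=lambda: list(DEFAULT_GRID))
    orders: tuple[int, int, int] = (2, 1, 1)  # (p, q, n) when no grid search
    select_order: bool = False
    hblend: HBlendParams = field(default_factory=HBlendParams)
    min_days: int = 34
    adaptation_days: int = 7
    reml_tol: float = 1e-8
    reml_max_iter: int = 500
    cutoff_date: date | str | None = None
    garrick_c: float = 0.5
    r2_floor: float = 0.10

    def __post_init__(self) -> None:
        has_paths = self.pedigree_path is not None
        if self.sim is None and not has_paths:
            raise ValueError("config needs either a 'sim' block or input paths")
        if self.sim is not None and has_paths:
            raise ValueError("give either a 'sim' block or input paths, not both")
        if abs(self.hblend.alpha + self.hblend.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if self.min_days < 0:
            raise ValueError("min_days must be >= 0")
        if self.adaptation_days < 0:
            raise ValueError("adaptation_days must be >= 0")
        if not self.grid:
            raise ValueError("empty model-order grid")


_SIM_KEYS = set(SimConfig.__dataclass_fields__)
_TOP_KEYS = set(PipelineConfig.__dataclass_fields__)
_HB_KEYS = set(HBlendParams.__dataclass_fields__)


def validate_config(raw: dict) -> PipelineConfig:
    """Normalise a raw (e.g. YAML-loaded) mapping into a PipelineConfig.

    Unknown keys are rejected; omitted optional blocks materialise the
    documented defaults.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimConfig):
        sim_raw = dict(raw["sim"])
        bad = set(sim_raw) - _SIM_KEYS
        if bad:
            raise ValueError(f"unknown sim keys: {sorted(bad)}")
        for key in ("Ka_true", "Kpe_true", "Klitter_true"):
            if key in sim_raw:
                sim_raw[key] = np.asarray(sim_raw[key], dtype=float)
        for key in ("maf_range", "age_range", "window_range", "visit_range", "betas"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim_raw.setdefault("seed", raw.get("seed", 0))
        raw["sim"] = SimConfig(**sim_raw)
    if "hblend" in raw and raw["hblend"] is not None and not isinstance(raw["hblend"], HBlendParams):
        hb = dict(raw["hblend"])
        bad = set(hb) - _HB_KEYS
        if bad:
            raise ValueError(f"unknown hblend keys: {sorted(bad)}")
        raw["hblend"] = HBlendParams(**hb)
    if "grid" in raw and raw["grid"] is not None:
        raw["grid"] = [tuple(int(v) for v in cell) for cell in raw["grid"]]
    if "orders" in raw and raw["orders"] is not None:
        raw["orders"] = tuple(int(v) for v in raw["orders"])
    return PipelineConfig(**raw)


def config_fingerprint(cfg: PipelineConfig) -> str:
    """Stable hash of the scientific configuration (output path excluded)."""
    import hashlib
    import json

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (date,)):
            return o.isoformat()
        return str(o)

    payload = asdict(cfg)
    payload.pop("outdir", None)
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
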