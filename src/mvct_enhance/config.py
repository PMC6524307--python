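"""Run configuration: the published parameter set as the single source of
truth, plus a flat ``key = value`` config-file format.

Defaults (the method's reference settings): 8x8 patches, groups of 5
blocks, a 39x39 search window, sliding interval 3 px, distance cap 400,
sparsity cap 10, 8x8x5 dictionary atoms, and a 400/40 HU soft-tissue
display window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .block_matching import MatchConfig
from .dictionary import DictionaryConfig
from .errors import ConfigurationError, ValidationError
from .image_io import WindowingSpec
from .pipeline import PipelineConfig


@dataclass
class RunConfig:
    # block matching
    n_block: int = 8
    n_number: int = 5
    search_window: int = 39
    step: int = 3
    tau_match: float = 400.0
    lambda_2d: float = 0.0
    # sparse coding / dictionary
    c_dfr: int = 10
    atom_nx: int = 8
    atom_ny: int = 8
    atom_nz: int = 5
    k_hq: int = 256
    k_na: int = 256
    rho_max: float = 0.9
    dict_stride: int = 4
    # collaborative filtering
    lambda_3d: float = 2.7
    sigma: float = -1.0          # < 0 -> estimate from the image
    # windowing
    window_width: float = 400.0
    window_level: float = 40.0
    # run control
    method: str = "bm3d_dfr"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        # route validation through the component configs so errors carry
        # the offending key's name
        try:
            self.match_config()
        except ValidationError as e:
            raise ConfigurationError(f"invalid block-matching settings: {e}") from e
        if self.n_block < 2:
            raise ConfigurationError("n_block must be >= 2")
        if self.c_dfr < 1:
            raise ConfigurationError("c_dfr must be >= 1")
        if min(self.atom_nx, self.atom_ny, self.atom_nz) < 1:
            raise ConfigurationError("atom_nx/atom_ny/atom_nz must be >= 1")
        if self.window_width <= 0:
            raise ConfigurationError("window_width must be > 0")
        if self.method not in {"bm3d", "bm3d_dfr"}:
            raise ConfigurationError(f"method must be bm3d or bm3d_dfr, got {self.method!r}")

    # -- component views ----------------------------------------------------

    def windowing(self) -> WindowingSpec:
        return WindowingSpec(self.window_width, self.window_level)

    def match_config(self) -> MatchConfig:
        return MatchConfig(
            n_block=self.n_block, n_number=self.n_number,
            window=self.search_window, step=self.step,
            tau_match=self.tau_match, lambda_2d=self.lambda_2d)

    def pipeline_config(self, method: "str | None" = None) -> PipelineConfig:
        return PipelineConfig(
            match=self.match_config(),
            lambda_3d=self.lambda_3d,
            sigma=None if self.sigma < 0 else self.sigma,
            method=method or self.method,
            c_dfr=self.c_dfr,
            window=self.windowing())

    def dictionary_config(self) -> DictionaryConfig:
        return DictionaryConfig(
            atom_dims=(self.atom_nx, self.atom_ny, self.atom_nz),
            stride=self.dict_stride, k_hq=self.k_hq, k_na=self.k_na,
            rho_max=self.rho_max, seed=self.seed, window=self.windowing())


def _parse_value(key: str, raw: str, target_type: type):
    raw = raw.strip()
    try:
        if target_type is bool:
            if raw.lower() in {"true", "1", "yes"}:
                return True
            if raw.lower() in {"false", "0", "no"}:
                return False
            raise ValueError(raw)
        return target_type(raw)
    except ValueError as e:
        raise ConfigurationError(f"invalid value for {key}: {raw!r}") from e


def load_config(path=None, overrides: "dict | None" = None) -> RunConfig:
    """Build a RunConfig from a flat ``key = value`` file plus overrides.

    Unknown keys are rejected with the offending key named; an absent file
    and empty overrides yield the reference defaults.
    """
    known = {f.name: f.type for f in fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected 'key = value'")
            key, raw = (t.strip() for t in line.split("=", 1))
            if key not in known:
                raise ConfigurationError(f"unknown configuration key: {key}")
            values[key] = _parse_value(key, raw, types[key])
    for key, val in (overrides or {}).items():
        if key not in known:
            raise ConfigurationError(f"unknown configuration key: {key}")
        values[key] = _parse_value(key, str(val), types[key]) if isinstance(val, str) else val
    return RunConfig(**values)


def dump_config(cfg: RunConfig) -> str:
    """Serialize to the flat text format; load(dump(c)) == c."""
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in fields(cfg)]
    return "\n".join(lines) + "\n"
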