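"""Flat key-value configuration for the pipeline.

Format: one ``key = value`` pair per line, ``#`` comments, blank lines
ignored. Dotted keys group related settings::

    mode = synthetic
    seed = 1
    out = results/
    synthetic.n_cores = 10
    synthetic.r_true = 10
    band.mode = published
    ci.level = 0.99
    ci.n_boot = 10000

Real-data runs replace the ``synthetic.*`` block with ``inputs.*`` paths
(otu_table, taxonomy, samples, geochem, optional opd_table and candidates).
Exactly one of the two blocks must be present. The root ``seed`` is the
single seeding authority: stage seeds (simulation, bootstrap) are derived
from it, and a ``synthetic.seed`` key is rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .guilds import GuildConfig
from .synthetic import SyntheticParams

_SYNTH_FLOAT_FIELDS = {
    "opd_cm", "o2_surface_uM", "r_true", "f_candidate", "f_split_canonical",
    "aoa_surface_cells", "decay_per_cm", "background_mean_cells",
    "background_lognorm_sigma", "qpcr_sigma", "anoxic_decay_per_cm",
    "candidate_anoxic_floor",
}
_SYNTH_INT_FIELDS = {"n_cores", "background_otus", "read_depth"}

_INPUT_KEYS = ("otu_table", "taxonomy", "samples", "geochem", "opd_table", "candidates")


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat key-value config file into a string dict."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key in values:
            raise ParameterError(f"{path}:{lineno}: duplicate key {key!r}")
        values[key] = value.strip()
    return values


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    synthetic: SyntheticParams | None = None
    inputs: dict[str, Path] | None = None
    guild_config: GuildConfig | None = None
    verified_candidate_otus: tuple[str, ...] | None = None
    band_mode: str = "published"
    ci_level: float = 0.99
    n_boot: int = 10000
    opd_threshold_uM: float = 1.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ParameterError(
                "config must contain exactly one of a synthetic block or input paths"
            )
        if self.inputs is not None:
            for key in ("otu_table", "taxonomy", "samples"):
                if key not in self.inputs:
                    raise ParameterError(f"inputs.{key} is required for a real-data run")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ParameterError(f"inputs.{key}: no such file {path}")
        if self.band_mode not in ("published", "computed"):
            raise ParameterError(f"band.mode must be published|computed, got {self.band_mode!r}")
        if not 0 < self.ci_level < 1:
            raise ParameterError("ci.level must be in (0, 1)")
        if self.n_boot < 1:
            raise ParameterError("ci.n_boot must be >= 1")

    def stage_seeds(self) -> dict[str, int]:
        """Derive per-stage seeds from the root seed (simulate, bootstrap)."""
        children = np.random.SeedSequence(self.seed).spawn(2)
        return {
            "simulate": int(children[0].generate_state(1)[0]) % (2**31),
            "bootstrap": int(children[1].generate_state(1)[0]) % (2**31),
        }


def _parse_synthetic(flat: dict[str, str]) -> SyntheticParams:
    kwargs: dict = {}
    for key, value in flat.items():
        if not key.startswith("synthetic."):
            continue
        field = key.removeprefix("synthetic.")
        if field == "seed":
            raise ParameterError(
                "synthetic.seed is not accepted; the root 'seed' governs all stages"
            )
        if field == "depths_cm":
            kwargs[field] = tuple(float(v) for v in value.split(","))
        elif field == "count_model":
            kwargs[field] = value
        elif field in _SYNTH_INT_FIELDS:
            kwargs[field] = int(value)
        elif field in _SYNTH_FLOAT_FIELDS:
            if field == "opd_cm" and "," in value:
                kwargs[field] = tuple(float(v) for v in value.split(","))
            else:
                kwargs[field] = float(value)
        else:
            raise ParameterError(f"unknown synthetic parameter {field!r}")
    return SyntheticParams(**kwargs)


def load_pipeline_config(
    path: str | Path,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineConfig:
    """Load a pipeline config file; ``seed`` and ``out_dir`` override the file."""
    flat = read_flat_config(path)
    mode = flat.get("mode")
    if mode not in ("synthetic", "real"):
        raise ParameterError(f"{path}: 'mode' must be synthetic|real, got {mode!r}")

    if seed is None:
        if "seed" not in flat:
            raise ParameterError(f"{path}: mandatory key 'seed' is missing")
        seed = int(flat["seed"])
    if out_dir is None:
        if "out" not in flat:
            raise ParameterError(f"{path}: mandatory key 'out' is missing")
        out_dir = flat["out"]

    synthetic = _parse_synthetic(flat) if mode == "synthetic" else None
    inputs = None
    if mode == "real":
        base = Path(path).parent
        inputs = {
            key: base / flat[f"inputs.{key}"]
            for key in _INPUT_KEYS
            if f"inputs.{key}" in flat
        }

    candidates = None
    if "candidates" in flat:
        candidates = tuple(v.strip() for v in flat["candidates"].split(",") if v.strip())

    config = PipelineConfig(
        seed=seed,
        out_dir=Path(out_dir),
        synthetic=synthetic,
        inputs=inputs,
        verified_candidate_otus=candidates,
        band_mode=flat.get("band.mode", "published"),
        ci_level=float(flat.get("ci.level", "0.99")),
        n_boot=int(flat.get("ci.n_boot", "10000")),
        opd_threshold_uM=float(flat.get("opd.threshold_uM", "1.0")),
        log_level=flat.get("log_level", "INFO"),
    )
    config.validate()
    return config
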