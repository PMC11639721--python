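"""Nested pipeline configuration with strict key validation.

YAML config files mirror the module surfaces::

    seed: 7
    io:       {lead: MLII, paced_records: ["102", "104", "107", "217"]}
    filter:   {order: 4, low_hz: 0.5, high_hz: 50.0}
    segment:  {pre: 144, post: 180}
    resample: {length: 64}
    imaging:  {rp_mode: binary, gaf_kind: gasf, mtf_bins: 8}
    fca:      {n_freq: 16, reduction: 16, strategy: lowest}
    model:    {image_size: 64, block_channels: [16, 32, 64, 128]}
    train:    {batch_size: 128, max_epochs: 80}
    smote:    {enabled: false, m_neighbors: 10, k_neighbors: 5}
    split:    {test_fraction: 0.2, val_fraction: 0.1}
    simulate: {n_beats: 300, noise: {}}

Unknown keys raise immediately; every value is validated by the dataclass
of the owning module.
"""

from __future__ import annotations

from dataclasses import MISSING, dataclass, field, fields
from pathlib import Path

import yaml

from .balance import SmoteConfig
from .fca import FcaConfig
from .imaging import ImagingConfig
from .network import ModelConfig, TrainConfig
from .wfdb_io import DEFAULT_PACED_RECORDS

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class IoSection:
    lead: str = "MLII"
    paced_records: list = field(default_factory=lambda: list(DEFAULT_PACED_RECORDS))


@dataclass
class FilterSection:
    order: int = 6
    low_hz: float = 0.5
    high_hz: float = 50.0


@dataclass
class SegmentSection:
    pre: int = 144
    post: int = 180


@dataclass
class ResampleSection:
    length: int = 224


@dataclass
class SplitSection:
    test_fraction: float = 0.2
    val_fraction: float = 0.1


@dataclass
class SmoteSection(SmoteConfig):
    enabled: bool = False


@dataclass
class SimulateSection:
    n_beats: int = 300
    fs: float = 360.0
    noise: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    io: IoSection = field(default_factory=IoSection)
    filter: FilterSection = field(default_factory=FilterSection)
    segment: SegmentSection = field(default_factory=SegmentSection)
    resample: ResampleSection = field(default_factory=ResampleSection)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    fca: FcaConfig = field(default_factory=FcaConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    smote: SmoteSection = field(default_factory=SmoteSection)
    split: SplitSection = field(default_factory=SplitSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)

    def resolved(self) -> dict:
        """Fully resolved plain-dict view, written next to every output."""
        def undata(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: undata(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [undata(v) for v in obj]
            if isinstance(obj, dict):
                return {k: undata(v) for k, v in obj.items()}
            return obj
        return undata(self)


def _build(cls, data: dict, path: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section '{path}'")
    kwargs = {}
    for key, value in data.items():
        factory = allowed[key].default_factory
        target = factory() if factory is not MISSING else None
        if hasattr(target, "__dataclass_fields__") and isinstance(value, dict):
            kwargs[key] = _build(type(target), value, f"{path}.{key}" if path else key)
        elif isinstance(value, list):
            kwargs[key] = value if key in ("paced_records", "custom_pairs") else tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file, dict, or defaults."""
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        data = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _build(PipelineConfig, data, "")
    if hasattr(cfg.model, "validate"):
        cfg.model.validate()
    cfg.train.validate()
    return cfg
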