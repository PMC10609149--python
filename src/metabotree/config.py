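"""Pipeline configuration: nested dataclasses mirroring the JSON config
schema, with load-time validation that reports dotted field paths."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .dimred import TSNEConfig
from .errors import ValidationError
from .nnet import MLPConfig
from .preprocess import DiscretizationSpec, FilterSpec

__all__ = ["StageConfig", "EvalConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class StageConfig:
    """Per-stage dimensionality-reduction choice and its parameters."""

    dimred: str = "tsne"  # 'tsne' or 'pca'
    tsne: TSNEConfig = field(default_factory=TSNEConfig)
    pca_components: int = 3
    oos: str = "transductive"  # out-of-sample policy: 'transductive' | 'knn_map'
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.dimred not in ("tsne", "pca"):
            raise ValidationError(f"dimred must be 'tsne' or 'pca', got {self.dimred!r}")
        if self.oos not in ("transductive", "knn_map"):
            raise ValidationError(f"oos must be 'transductive' or 'knn_map', got {self.oos!r}")
        if self.pca_components < 1:
            raise ValidationError("pca_components must be >= 1")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


@dataclass(frozen=True)
class EvalConfig:
    k_folds: int = 5
    stratified: bool = True
    seed: int = 0
    ns_frac_override: float | None = None
    sc_frac_override: float | None = None

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        for name in ("ns_frac_override", "sc_frac_override"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    discretize: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    select_k: int = 170
    select_log_base: float = 2.0
    clamp_k: bool = True  # shrink k to the column count instead of erroring
    normalize_scope: str = "train_only"  # or 'pooled'
    stage1: StageConfig = field(default_factory=StageConfig)
    stage2: StageConfig = field(default_factory=StageConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.select_k < 1:
            raise ValidationError("select.k must be >= 1")
        if self.select_log_base <= 1:
            raise ValidationError("select.log_base must be > 1")
        if self.normalize_scope not in ("train_only", "pooled"):
            raise ValidationError(
                f"normalize_scope must be 'train_only' or 'pooled', got {self.normalize_scope!r}"
            )

    def to_dict(self) -> dict:
        """Resolved-config echo, sufficient to reproduce a run."""
        def encode(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = encode(self)
        d["select"] = {"k": d.pop("select_k"), "log_base": d.pop("select_log_base")}
        return d


def _build(cls, data: dict, path: str):
    """Construct a (frozen) dataclass from a dict, reporting dotted paths."""
    if not isinstance(data, dict):
        raise ValidationError(f"{path or 'config'}: expected an object")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"{path or 'config'}: unknown field(s) {sorted(unknown)}")
    kwargs = {}
    sub_types = {
        "filter": FilterSpec,
        "discretize": DiscretizationSpec,
        "tsne": TSNEConfig,
        "stage1": StageConfig,
        "stage2": StageConfig,
        "mlp": MLPConfig,
        "eval": EvalConfig,
    }
    for key, value in data.items():
        child = f"{path}.{key}" if path else key
        if key in sub_types and isinstance(value, dict):
            kwargs[key] = _build(sub_types[key], value, child)
        elif key == "hidden_sizes":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValidationError, TypeError) as exc:
        raise ValidationError(f"{path or 'config'}: {exc}") from None


def config_from_dict(data: dict) -> PipelineConfig:
    """Parse the JSON config schema (with a nested ``select`` block)."""
    data = dict(data)
    select = data.pop("select", None)
    if select is not None:
        if not isinstance(select, dict):
            raise ValidationError("select: expected an object")
        if "k" in select:
            data["select_k"] = select["k"]
        if "log_base" in select:
            data["select_log_base"] = select["log_base"]
        unknown = set(select) - {"k", "log_base"}
        if unknown:
            raise ValidationError(f"select: unknown field(s) {sorted(unknown)}")
    try:
        return _build(PipelineConfig, data, "")
    except ValidationError as exc:
        # surface select.k style paths for the flattened fields
        msg = str(exc).replace("select_k", "select.k").replace("select_log_base", "select.log_base")
        raise ValidationError(msg) from None


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a JSON config file; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return config_from_dict(json.load(fh))
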