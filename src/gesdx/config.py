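"""Run configuration: what to analyse, with which methods, written where."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .roc import InvalidInputError
from .simulate import GESCohortSpec

VALID_METHODS = ("LDA", "DF", "CART")


@dataclass
class RunConfig:
    """Configuration of a full simulate -> fit -> validate -> report run.

    ``input_path`` points at an existing cohort CSV; when it is empty a
    synthetic cohort is generated from ``generator`` (whose seed is tied to
    ``seed``).  ``markers`` selects the linear-combination time points;
    ``cart_markers``/``covariates`` the tree's feature set.
    """

    input_path: str = ""
    generator: dict = field(default_factory=dict)
    markers: tuple[str, ...] = ("h3", "h4")
    cart_markers: tuple[str, ...] = ("h1", "h2", "h3", "h4")
    covariates: tuple[str, ...] = ("age", "sex")
    methods: tuple[str, ...] = ("LDA", "DF", "CART")
    transform: bool = False
    levels: tuple[float, ...] = (0.7, 0.8, 0.9)
    grid_step: float = 0.25
    refinement_rounds: int = 2
    cart_min_node_size: int = 10
    cart_criterion: str = "deviance"
    cart_cv_folds: int = 10
    seed: int = 0
    output_dir: str = "gesdx_run"
    simulate_only: bool = False

    def __post_init__(self):
        for coerce in ("markers", "cart_markers", "covariates", "methods", "levels"):
            setattr(self, coerce, tuple(getattr(self, coerce)))
        if not self.methods and not self.simulate_only:
            raise InvalidInputError("at least one method is required")
        bad = [m for m in self.methods if m not in VALID_METHODS]
        if bad:
            raise InvalidInputError(f"unknown method(s): {bad}")
        if not self.markers:
            raise InvalidInputError("marker subset must be non-empty")
        if any(not (0 < lv < 1) for lv in self.levels):
            raise InvalidInputError("sensitivity levels must lie in (0,1)")

    def cohort_spec(self) -> GESCohortSpec:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        return GESCohortSpec(**kwargs)

    def to_yaml(self, path) -> None:
        d = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)
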