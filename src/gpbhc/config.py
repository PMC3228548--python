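"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


CRP_ALPHA_GRID = (1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class RunConfig:
    """Settings for a clustering run.

    ``crp_alpha`` is the Dirichlet-process concentration; the string
    ``"grid"`` selects the best value from a small grid by root tree
    log marginal likelihood.
    """

    kernel: str = "SE"
    mixture_on: bool = False
    use_replicate_prior: bool = True
    crp_alpha: float | str = 1e-3
    omega: float = 100.0
    n_restarts: int = 3
    gtol: float = 1e-6
    maxiter: int = 200
    seed: int = 0
    partition_threshold: float = 0.5
    input_path: str | None = None
    sidecar_path: str | None = None
    output_dir: str | None = None
    annotation_path: str | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("SE", "CS"):
            raise ValueError(f"kernel must be 'SE' or 'CS', got {self.kernel!r}")
        if isinstance(self.crp_alpha, str):
            if self.crp_alpha != "grid":
                raise ValueError("crp_alpha must be a positive number or 'grid'")
        elif self.crp_alpha <= 0:
            raise ValueError("crp_alpha must be positive")
        if not (0.0 <= self.partition_threshold <= 1.0):
            raise ValueError("partition_threshold must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)
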