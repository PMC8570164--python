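"""Flat ``key = value`` run-configuration files.

Recognized keys (all optional except ``model``):

    model                normal_conjugate | beta_binomial | phylo_gtr
    stones               number of powers K                (default 100)
    alpha                beta-quantile shape               (default 0.3)
    iterations           sweeps per stone L                (default 10000)
    thinning             record every T-th sweep           (default 10)
    burnin_frac          per-stone sample burn-in          (default 0.25)
    preburn_iters        pre-burn-in sweeps                (default 10000)
    seed                 root RNG seed                     (default 0)
    workers              worker count M                    (default 1)
    cpus_per_likelihood  CPUs per likelihood N             (default 1)
    alignment            FASTA/PHYLIP path   (phylo_gtr only)
    tree                 newick path         (phylo_gtr only)
    output_dir           where sample files are written

Unknown keys are errors, not warnings: a typo must not silently fall back
to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .sampler import StoneRunConfig

__all__ = ["RunConfig", "parse_config", "build_model"]

_KEYS = {
    "model": str,
    "stones": int,
    "alpha": float,
    "iterations": int,
    "thinning": int,
    "burnin_frac": float,
    "preburn_iters": int,
    "seed": int,
    "workers": int,
    "cpus_per_likelihood": int,
    "alignment": str,
    "tree": str,
    "output_dir": str,
}

_MODELS = {"normal_conjugate", "beta_binomial", "phylo_gtr"}


@dataclass
class RunConfig:
    model: str = "normal_conjugate"
    stones: int = 100
    alpha: float = 0.3
    iterations: int = 10_000
    thinning: int = 10
    burnin_frac: float = 0.25
    preburn_iters: int = 10_000
    seed: int = 0
    workers: int = 1
    cpus_per_likelihood: int = 1
    alignment: str | None = None
    tree: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_MODELS)}")

    def stone_run_config(self) -> StoneRunConfig:
        return StoneRunConfig(
            L=self.iterations,
            T=self.thinning,
            burnin_frac=self.burnin_frac,
            preburn_iters=self.preburn_iters,
            seed=self.seed,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _KEYS}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a flat key = value file; blank lines and '#' comments allowed."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in _KEYS:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        values[key] = _KEYS[key](value)
    return RunConfig(**values)


def build_model(config: RunConfig):
    """Instantiate the target model named by the configuration."""
    if config.model == "normal_conjugate":
        from .models.reference import default_normal_model

        return default_normal_model()
    if config.model == "beta_binomial":
        from .models.reference import default_betabinom_model

        return default_betabinom_model()
    # phylo_gtr
    from .models.phylo import PhyloGTRModel, read_alignment, read_tree

    if not config.alignment or not config.tree:
        raise ValueError("phylo_gtr requires the 'alignment' and 'tree' keys")
    return PhyloGTRModel(
        tree=read_tree(config.tree),
        alignment=read_alignment(config.alignment),
        N=config.cpus_per_likelihood,
    )
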