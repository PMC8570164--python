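"""End-to-end power posterior analyses: sequential, parallel, and resumable.

The parallel algorithm mirrors the sequential one: the K stones are split
into M consecutive blocks; every worker runs its own pre-burn-in (at its
block's highest power) and then its stones in decreasing-power order,
threading chain state between them.  Workers never communicate; the single
synchronization barrier is at the end, when the master merges the
per-worker sample files and hands the assembled matrix to the estimators.

Determinism contract: worker w derives the stream for phase position p
(0 = pre-burn-in, then one per stone) from ``SeedSequence([seed, w, p])``.
The multi-process backend and the in-process serial emulation therefore
produce bit-identical sample files, and an M=1 parallel run is bit-identical
to the sequential runner.

The expected-runtime model captures the parallel overhead analytically:
with a pre-burn-in costing one stone, M CPUs need
``t1 * (ceil(K/M) + 1) / (K + 1)`` where t1 is the measured single-CPU time.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import SampleMatrix
from .sampler import ParameterState, StoneRunConfig, StoneSamples, run_block, run_stone
from .schedule import BlockPlan, PowerSchedule, partition_blocks

__all__ = [
    "RuntimeModel",
    "RunManifest",
    "expected_runtime",
    "run_sequential",
    "run_parallel",
    "merge_samples",
    "resume",
    "write_worker_samples",
    "read_worker_samples",
]


# ---------------------------------------------------------------------------
# Expected-runtime model


@dataclass(frozen=True)
class RuntimeModel:
    """Inputs of the expected-runtime formula for M CPUs."""

    t1: float  # measured single-CPU runtime, seconds
    K: int
    M: int

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.K < 1 or self.M < 1:
            raise ValueError("K and M must be >= 1")


def expected_runtime(rm: RuntimeModel) -> float:
    """Expected wall time on M CPUs: t1 * (ceil(K/M) + 1) / (K + 1).

    Each CPU runs at most ceil(K/M) stones plus its own pre-burn-in, and the
    single-CPU run amounts to K stones plus one pre-burn-in, so t1/(K+1) is
    the per-stone cost.
    """
    return rm.t1 * (math.ceil(rm.K / rm.M) + 1) / (rm.K + 1)


# ---------------------------------------------------------------------------
# Sample files (bit-exact TSV round trip)

_HEADER = ["stone", "power", "iteration", "log_likelihood"]


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_worker_samples(path: str | Path, stones: list[StoneSamples]) -> None:
    """Write one worker's stones as TSV, grouped by stone, decreasing power.

    Powers and log-likelihoods are printed with 17 significant digits so the
    doubles round-trip losslessly.
    """
    ordered = sorted(stones, key=lambda s: -s.beta)
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for s in ordered:
            beta = _fmt(s.beta)
            for it, ll in zip(s.iterations, s.log_likelihoods):
                fh.write(f"{s.stone}\t{beta}\t{int(it)}\t{_fmt(ll)}\n")


def read_worker_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != _HEADER:
        raise ValueError(f"{path}: expected columns {_HEADER}, got {list(df.columns)}")
    return df


def merge_samples(paths: list[str | Path]) -> SampleMatrix:
    """Merge per-worker sample files into one matrix.

    Validates that stone indices 0..K-1 each appear exactly once across the
    files with a common per-stone sample count; missing or duplicated stones
    are named in the error.
    """
    frames = [read_worker_samples(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    groups = {int(k): g for k, g in df.groupby("stone")}
    K = max(groups) + 1 if groups else 0
    missing = sorted(set(range(K)) - set(groups))
    if missing or K < 2:
        raise ValueError(f"missing stones in sample files: {missing or 'all'}")
    counts = {k: len(g) for k, g in groups.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal per-stone sample counts: {counts}")
    dup = df.groupby(["stone", "iteration"]).size()
    if (dup > 1).any():
        bad = sorted({int(s) for s, _ in dup[dup > 1].index})
        raise ValueError(f"duplicated samples for stones {bad}")
    powers = np.empty(K)
    samples = np.empty((K, next(iter(counts.values()))))
    for k, g in groups.items():
        power = g["power"].unique()
        if power.size != 1:
            raise ValueError(f"stone {k} has inconsistent powers {power}")
        powers[k] = power[0]
        samples[k] = g.sort_values("iteration")["log_likelihood"].to_numpy()
    return SampleMatrix(powers=powers, samples=samples)


# ---------------------------------------------------------------------------
# Manifest


@dataclass
class RunManifest:
    """Everything needed to audit or resume a run."""

    config: dict
    K: int
    M: int
    N: int
    seed: int
    blocks: list[list[int]]  # ascending-order stone indices per worker
    powers: list[float]  # ascending
    completed: dict[int, bool] = field(default_factory=dict)
    init_states: dict[int, dict] = field(default_factory=dict)  # stone -> values
    worker_files: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "K": self.K,
            "M": self.M,
            "N": self.N,
            "seed": self.seed,
            "blocks": [list(map(int, b)) for b in self.blocks],
            "powers": self.powers,
            "completed": {str(k): v for k, v in self.completed.items()},
            "init_states": {str(k): v for k, v in self.init_states.items()},
            "worker_files": self.worker_files,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            config=d["config"],
            K=d["K"],
            M=d["M"],
            N=d["N"],
            seed=d["seed"],
            blocks=d["blocks"],
            powers=d["powers"],
            completed={int(k): v for k, v in d["completed"].items()},
            init_states={int(k): v for k, v in d["init_states"].items()},
            worker_files=d["worker_files"],
        )


def _values_to_json(values: dict) -> dict:
    return {
        k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
        for k, v in values.items()
    }


def _values_from_json(values: dict) -> dict:
    return {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else float(v))
        for k, v in values.items()
    }


# ---------------------------------------------------------------------------
# Runners


def _phase_rng(seed: int, worker: int, position: int) -> np.random.Generator:
    """Independent stream for worker ``worker``, phase ``position``
    (0 = pre-burn-in, then one stream per stone)."""
    return np.random.default_rng(np.random.SeedSequence([seed, worker, position]))


def _worker_task(args) -> tuple[list, dict]:
    """Run one worker's block; also record each stone's starting state so an
    interrupted run can be resumed stone by stone.

    Equivalent to :func:`powerpost.sampler.run_block` with per-phase streams
    from :func:`_phase_rng`.
    """
    from .sampler import pre_burnin

    model, stone_pairs, config, seed, worker = args
    state, _ = pre_burnin(model, config, stone_pairs[0][1], _phase_rng(seed, worker, 0))
    stones: list[StoneSamples] = []
    init_states: dict[int, dict] = {}
    for pos, (k, beta) in enumerate(stone_pairs, start=1):
        init_states[k] = _values_to_json(state.values)
        samples = run_stone(model, beta, state, config, _phase_rng(seed, worker, pos), stone=k)
        state = samples.final_state
        stones.append(samples)
    return stones, init_states


def _block_stone_pairs(
    schedule: PowerSchedule, plan: BlockPlan, worker: int
) -> list[tuple[int, float]]:
    ascending = schedule.ascending
    return [(int(k), float(ascending[k])) for k in plan.blocks[worker]]


def run_sequential(
    model,
    schedule: PowerSchedule,
    config: StoneRunConfig,
    output_dir: str | Path | None = None,
) -> SampleMatrix:
    """Run all K stones in one block on the calling process."""
    return run_parallel(model, schedule, config, M=1, backend="serial", output_dir=output_dir)


def run_parallel(
    model,
    schedule: PowerSchedule,
    config: StoneRunConfig,
    M: int = 1,
    N: int = 1,
    backend: str = "serial",
    output_dir: str | Path | None = None,
) -> SampleMatrix:
    """Run the schedule over M workers and merge the results.

    ``backend="process"`` uses a process pool; ``backend="serial"`` emulates
    the same block plan in-process.  Both produce bit-identical sample files
    for the same seed.  If ``output_dir`` is given, per-worker TSV files, a
    merged ``samples_all.tsv``, and a ``manifest.json`` are written there.
    """
    plan = partition_blocks(schedule, M)
    tasks = [
        (model, _block_stone_pairs(schedule, plan, w), config, config.seed, w)
        for w in range(M)
    ]
    if backend == "process":
        with ProcessPoolExecutor(max_workers=M) as pool:
            results = list(pool.map(_worker_task, tasks))
    elif backend == "serial":
        results = [_worker_task(t) for t in tasks]
    else:
        raise ValueError(f"unknown backend {backend!r}")
    per_worker = [stones for stones, _ in results]
    init_states = {k: v for _, states in results for k, v in states.items()}

    all_stones = [s for block in per_worker for s in block]
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        worker_files = []
        for w, block in enumerate(per_worker):
            fname = output_dir / f"samples_worker{w}.tsv"
            write_worker_samples(fname, block)
            worker_files.append(fname.name)
        write_worker_samples(output_dir / "samples_all.tsv", all_stones)
        manifest = RunManifest(
            config={
                "L": config.L,
                "T": config.T,
                "burnin_frac": config.burnin_frac,
                "preburn_iters": config.preburn_iters,
            },
            K=schedule.K,
            M=M,
            N=N,
            seed=config.seed,
            blocks=[list(map(int, b)) for b in plan.blocks],
            powers=[float(p) for p in schedule.ascending],
            completed={s.stone: True for s in all_stones},
            init_states=init_states,
            worker_files=worker_files,
        )
        manifest.save(output_dir / "manifest.json")
    powers = np.array(sorted(s.beta for s in all_stones))
    ordered = sorted(all_stones, key=lambda s: s.beta)
    samples = np.vstack([s.log_likelihoods for s in ordered])
    return SampleMatrix(powers=powers, samples=samples)


def resume(
    manifest: RunManifest,
    model,
    config: StoneRunConfig,
) -> list[StoneSamples]:
    """Re-run only the stones whose completion flags are false.

    Each incomplete stone is re-run with its recorded deterministic stream
    (derived from the manifest's seed, worker, and block position) and its
    recorded initial chain state.
    """
    redone: list[StoneSamples] = []
    powers = manifest.powers
    for w, block in enumerate(manifest.blocks):
        for pos, k in enumerate(block, start=1):
            if manifest.completed.get(int(k), False):
                continue
            if int(k) not in manifest.init_states:
                raise ValueError(f"stone {k} incomplete but has no recorded start state")
            init = ParameterState(values=_values_from_json(manifest.init_states[int(k)]))
            rng = _phase_rng(manifest.seed, w, pos)
            samples = run_stone(model, float(powers[int(k)]), init, config, rng, stone=int(k))
            manifest.completed[int(k)] = True
            redone.append(samples)
    return redone
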