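"""The two-step structure search: rank structures, then permute widths.

Step 1 trains every enumerated structure at each of a small set of constant
layer widths (default 10, 20, 40, 80 — the constant-width replicates remove
bias toward any one fixed dimension) and ranks structures by their best
validation error.  The five lowest-error structures move on.  Step 2
exhaustively permutes the layer widths of those five structures over a
per-dataset option set (e.g. 32/64/128), trains every permutation, and
re-ranks.  The selected optimum is the lowest-error width-permuted network.

Every trained network is appended to a JSONL ledger keyed by a
deterministic trial id, so an interrupted search resumes without retraining
anything already recorded, and a re-run of a finished search is a pure
ledger replay.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arch_space import NetworkStructure, encode_structure, permute_widths
from .data_io import DatasetBundle
from .trainer import TrainConfig, TrialResult, train_model

__all__ = [
    "TrialLedger",
    "SearchReport",
    "run_structure_step",
    "run_width_step",
    "run_search",
    "improvement_over_average",
    "evaluate_test",
]


def _trial_id(encoding: str, config: TrainConfig, tag: str) -> str:
    payload = json.dumps(
        {
            "encoding": encoding,
            "tag": tag,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "patience": config.patience,
            "max_epochs": config.max_epochs,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


class TrialLedger:
    """Append-only JSONL record of trained networks, enabling resume."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._records: dict[str, TrialResult] = {}
        if self.path is not None and self.path.exists():
            with open(self.path) as fh:
                for line in fh:
                    if line.strip():
                        rec = json.loads(line)
                        self._records[rec["trial_id"]] = TrialResult.from_record(rec)

    def __len__(self) -> int:
        return len(self._records)

    def get(self, trial_id: str) -> TrialResult | None:
        return self._records.get(trial_id)

    def record(self, trial_id: str, result: TrialResult) -> None:
        self._records[trial_id] = result
        if self.path is not None:
            rec = {"trial_id": trial_id, **result.to_record()}
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")

    def results(self) -> list[TrialResult]:
        return list(self._records.values())


def _train_cached(
    structure: NetworkStructure,
    train: DatasetBundle,
    val: DatasetBundle,
    config: TrainConfig,
    ledger: TrialLedger,
    tag: str,
) -> TrialResult:
    encoding = encode_structure(structure, include_widths=True)
    tid = _trial_id(encoding, config, tag)
    cached = ledger.get(tid)
    if cached is not None:
        return cached
    try:
        result = train_model(structure, train, val, config)
    except FloatingPointError:  # pragma: no cover - defensive
        result = TrialResult(encoding, [1.0], 1, 1.0, True, config.seed, failed=True)
    ledger.record(tid, result)
    return result


def _with_uniform_width(structure: NetworkStructure, width: int) -> NetworkStructure:
    return permute_widths(structure, [width])[0]


@dataclass
class SearchReport:
    """Ranked outcome of both search steps and the selected optimum."""

    step1_ranking: list[tuple[NetworkStructure, float]]
    top5: list[NetworkStructure]
    step2_ranking: list[tuple[NetworkStructure, float]]
    best_network: NetworkStructure
    step1_improvement: float
    step2_improvement: float

    @property
    def improvement_over_average(self) -> float:
        """Percentage points between the mean and best step-2 error."""
        return self.step2_improvement

    def to_record(self) -> dict:
        def rank_rec(ranking):
            return [
                {"encoding": encode_structure(s, include_widths=True), "score": score}
                for s, score in ranking
            ]

        return {
            "step1_ranking": rank_rec(self.step1_ranking),
            "top5": [encode_structure(s, include_widths=True) for s in self.top5],
            "step2_ranking": rank_rec(self.step2_ranking),
            "best_network": encode_structure(self.best_network, include_widths=True),
            "step1_improvement": self.step1_improvement,
            "step2_improvement": self.step2_improvement,
        }


def improvement_over_average(ranking: list[tuple[NetworkStructure, float]]) -> float:
    """Mean error minus best error of a ranking, in percentage points."""
    if not ranking:
        raise ValueError("ranking must be non-empty")
    scores = np.array([score for _, score in ranking])
    return float((scores.mean() - scores.min()) * 100.0)


def _sorted_ranking(entries, tie_key):
    """Sort ascending by score, breaking ties deterministically."""
    return sorted(entries, key=lambda e: (e[1], *tie_key(e[0])))


def run_structure_step(
    structures: list[NetworkStructure],
    train: DatasetBundle,
    val: DatasetBundle,
    config: TrainConfig,
    widths: tuple[int, ...] = (10, 20, 40, 80),
    ledger: TrialLedger | None = None,
    aggregate: str = "min",
    progress: bool = False,
) -> list[tuple[NetworkStructure, float]]:
    """Train every structure at each constant width; rank by best error.

    A structure's score is the minimum (or, with ``aggregate='mean'``, the
    mean) of its best validation errors across the constant-width
    replicates.  Ties break toward lower VC-dimension, then canonical
    encoding.  Failed trials score 1.0.
    """
    if not structures:
        raise ValueError("structure list must be non-empty")
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    ledger = ledger if ledger is not None else TrialLedger()
    iterator = structures
    if progress:
        from tqdm import tqdm

        iterator = tqdm(structures, desc="structure step")
    entries = []
    for structure in iterator:
        errors = []
        for width in widths:
            candidate = _with_uniform_width(structure, width)
            result = _train_cached(candidate, train, val, config, ledger, "step1")
            errors.append(result.best_val_error)
        score = min(errors) if aggregate == "min" else float(np.mean(errors))
        entries.append((structure, score))
    return _sorted_ranking(
        entries, lambda s: (s.vc_dimension, encode_structure(s))
    )


def run_width_step(
    top5: list[NetworkStructure],
    width_options: tuple[int, ...],
    train: DatasetBundle,
    val: DatasetBundle,
    config: TrainConfig,
    ledger: TrialLedger | None = None,
    progress: bool = False,
) -> list[tuple[NetworkStructure, float]]:
    """Train every width permutation of the top structures; merged ranking.

    Ties break toward fewer total weights (prefer the cheaper network at
    equal error), then canonical encoding.
    """
    ledger = ledger if ledger is not None else TrialLedger()
    candidates: list[NetworkStructure] = []
    for structure in top5:
        candidates.extend(permute_widths(structure, width_options))
    iterator = candidates
    if progress:
        from tqdm import tqdm

        iterator = tqdm(candidates, desc="width step")
    entries = []
    for candidate in iterator:
        result = _train_cached(candidate, train, val, config, ledger, "step2")
        entries.append((candidate, result.best_val_error))
    return _sorted_ranking(
        entries,
        lambda s: (s.total_weights, encode_structure(s, include_widths=True)),
    )


def run_search(
    structures: list[NetworkStructure],
    train: DatasetBundle,
    val: DatasetBundle,
    config: TrainConfig,
    step1_widths: tuple[int, ...] = (10, 20, 40, 80),
    step2_options: tuple[int, ...] = (32, 64, 128),
    ledger: TrialLedger | None = None,
    top_k: int = 5,
    progress: bool = False,
) -> SearchReport:
    """Run both search steps and assemble the report."""
    ledger = ledger if ledger is not None else TrialLedger()
    step1 = run_structure_step(
        structures, train, val, config, step1_widths, ledger, progress=progress
    )
    top = [s for s, _ in step1[:top_k]]
    step2 = run_width_step(
        top, step2_options, train, val, config, ledger, progress=progress
    )
    return SearchReport(
        step1_ranking=step1,
        top5=top,
        step2_ranking=step2,
        best_network=step2[0][0],
        step1_improvement=improvement_over_average(step1),
        step2_improvement=improvement_over_average(step2),
    )


def evaluate_test(
    network: NetworkStructure,
    train: DatasetBundle,
    val: DatasetBundle,
    test: DatasetBundle,
    config: TrainConfig,
) -> float:
    """Train ``network`` and report its error on a held-out test bundle.

    This is the explicit final evaluation: the test split plays no role in
    either ranking step and is consulted only here.
    """
    from .trainer import _Adam, _Model, _softmax_xent_grad, evaluate_error

    result = train_model(network, train, val, config)
    # replay the seeded run up to its best epoch, then score on test data
    rng = np.random.default_rng(config.seed)
    model = _Model(network, rng)
    params = model.parameters()
    opt = _Adam(params, config)
    for _epoch in range(max(result.best_epoch, 1)):
        order = rng.permutation(len(train))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(train.images[idx], train=True)
            loss, dlogits = _softmax_xent_grad(logits, train.labels[idx])
            if not np.isfinite(loss):
                return 1.0
            opt.step(params, model.backward(dlogits))
    return evaluate_error(model, test)
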