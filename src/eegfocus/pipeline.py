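"""End-to-end orchestration: records -> subband entropies -> feature
selection -> cross-validated classification, plus the three-step TQWT
parameter sweep and report writing.

The canonical run decomposes each preprocessed record (difference channel,
first-differenced) with the TQWT at Q = r = 3 and J = 26, computes the
four entropies over the 27 subbands (108 features), optionally screens
them (Kruskal-Wallis, p < 0.05) or selects a subset with one of the six
binary metaheuristics driven by a classifier's cross-validated accuracy,
and evaluates the final classifiers with pooled ten-fold CV.  Shorter
records cap J at the admissible maximum level.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    EntropyConfig,
    FeatureMatrix,
    extract_features,
    feature_names,
    kws_mask,
    kws_pvalues,
)
from .models import (
    CLASSIFIER_FAMILIES,
    ClassifierSpec,
    CVResult,
    cross_validate,
)
from .preprocess import EEGRecordPair, preprocess_record, read_record
from .selectors import (
    FitnessContext,
    MetaheuristicConfig,
    SelectionResult,
    run_selector,
)
from .synthetic import SynthConfig, generate_dataset
from .tqwt import decompose, design_params, max_levels

logger = logging.getLogger("eegfocus")

__all__ = [
    "RunConfig",
    "extract_feature_matrix",
    "make_wrapper_fitness",
    "sweep_step1",
    "sweep_step2",
    "sweep_step3",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``data`` is either a directory of two-column ASCII records (labels
    from filenames) or a :class:`~eegfocus.synthetic.SynthConfig`.
    ``selector`` is ``"none"``, ``"kws"`` or one of
    ``bba/bde/fa/ga/gwo/pso``; metaheuristic fitness is the
    ``fitness_family`` classifier's pooled CV accuracy on the masked
    features (``fitness_folds`` folds, decoupled from the final
    ``folds``-fold evaluation).
    """

    data: str | Path | SynthConfig
    Q: float = 3.0
    r: float = 3.0
    J: int = 26
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    selector: str = "none"
    selector_overrides: dict = field(default_factory=dict)
    fitness_family: str | None = None
    fitness_folds: int = 10
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES
    classifier_hyperparams: dict = field(default_factory=dict)
    folds: int = 10
    seed: int = 0
    out_dir: str | Path | None = None


def _load_records(data) -> list[EEGRecordPair]:
    if isinstance(data, SynthConfig):
        return generate_dataset(data)
    data = Path(data)
    if not data.is_dir():
        raise FileNotFoundError(f"record directory not found: {data}")
    paths = sorted(p for p in data.iterdir() if p.suffix.lower() in (".txt", ".dat"))
    if not paths:
        raise FileNotFoundError(f"no .txt/.dat record files under {data}")
    records = [read_record(p) for p in paths]
    unknown = sum(1 for r in records if r.label == "unknown")
    if unknown:
        warnings.warn(f"{unknown} records have no class label in their filename")
    return records


def extract_feature_matrix(
    records: list[EEGRecordPair],
    Q: float,
    r: float,
    J: int,
    entropy_cfg: EntropyConfig | None = None,
    cap_levels: bool = True,
) -> FeatureMatrix:
    """Preprocess and decompose every record, returning the entropy table.

    When ``cap_levels`` is set, J is truncated to the maximum admissible
    level for the (differenced) record length, with a warning.
    """
    if not records:
        raise ValueError("no records to process")
    entropy_cfg = entropy_cfg or EntropyConfig()
    signals = [preprocess_record(rec) for rec in records]
    n = len(signals[0])
    jmax = max_levels(n, Q, r)
    j_eff = J
    if J > jmax:
        if not cap_levels:
            raise ValueError(f"J={J} exceeds max_levels={jmax} for n={n}")
        warnings.warn(f"J={J} exceeds max_levels={jmax} for n={n}; using J={jmax}")
        j_eff = jmax
    params = design_params(Q, r, j_eff)
    rows = []
    for i, sig in enumerate(signals):
        try:
            rows.append(extract_features(decompose(sig, params), entropy_cfg))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on record {i} "
                f"(label={records[i].label}): {exc}"
            ) from exc
    labels = np.array([rec.label for rec in records])
    return FeatureMatrix(np.vstack(rows), labels, feature_names(j_eff))


def make_wrapper_fitness(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
) -> FitnessContext:
    """Wrapper fitness: the classifier's pooled CV accuracy (percent) on
    the features a mask keeps.  Deterministic for fixed seed."""

    def evaluate(mask: np.ndarray) -> float:
        sub = matrix.select(np.asarray(mask, dtype=bool))
        return cross_validate(spec, sub, folds=folds, seed=seed).metrics.acc

    return FitnessContext(evaluate=evaluate, dimension=matrix.n_features)


# --------------------------------------------------------------------------
# Three-step TQWT parameter selection
# --------------------------------------------------------------------------


def sweep_step1(
    records: list[EEGRecordPair],
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES,
    folds: int = 10,
    seed: int = 0,
    entropy_cfg: EntropyConfig | None = None,
) -> list[tuple[str, CVResult]]:
    """Step 1: rank classifiers on all features at fixed Q = r = 2, J = 5."""
    if len(classifiers) < 2:
        raise ValueError("step 1 compares at least two classifiers")
    matrix = extract_feature_matrix(records, Q=2, r=2, J=5, entropy_cfg=entropy_cfg)
    results = []
    for family in classifiers:
        spec = ClassifierSpec(family, {}, seed)
        results.append((family, cross_validate(spec, matrix, folds=folds, seed=seed)))
    results.sort(key=lambda fr: -fr[1].metrics.acc)
    return results


def sweep_step2(
    records: list[EEGRecordPair],
    spec: ClassifierSpec,
    q_values=tuple(range(2, 11)),
    r_values=tuple(range(2, 6)),
    J: int = 5,
    folds: int = 10,
    seed: int = 0,
    entropy_cfg: EntropyConfig | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Step 2: accuracy surface over Q in 2..10 and r in 2..5 at fixed J.

    Ties break toward smaller Q, then smaller r.
    """
    rows = []
    best = (None, None, -np.inf)
    for q in q_values:
        for r in r_values:
            matrix = extract_feature_matrix(
                records, Q=q, r=r, J=J, entropy_cfg=entropy_cfg
            )
            acc = cross_validate(spec, matrix, folds=folds, seed=seed).metrics.acc
            rows.append({"Q": q, "r": r, "acc": acc})
            if acc > best[2]:
                best = (q, r, acc)
    return best[0], best[1], pd.DataFrame(rows)


def sweep_step3(
    records: list[EEGRecordPair],
    spec: ClassifierSpec,
    Q: float,
    r: float,
    j_values=tuple(range(5, 36)),
    folds: int = 10,
    seed: int = 0,
    entropy_cfg: EntropyConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Step 3: accuracy per decomposition level J, capped at max_levels.

    Levels exceeding the admissible maximum for the record length are
    skipped with a warning; ties break toward smaller J.
    """
    n = len(preprocess_record(records[0]))
    jmax = max_levels(n, Q, r)
    rows = []
    best = (None, -np.inf)
    for j in j_values:
        if j > jmax:
            warnings.warn(f"skipping J={j} > max_levels={jmax} for n={n}")
            continue
        matrix = extract_feature_matrix(
            records, Q=Q, r=r, J=j, entropy_cfg=entropy_cfg, cap_levels=False
        )
        acc = cross_validate(spec, matrix, folds=folds, seed=seed).metrics.acc
        rows.append({"J": j, "acc": acc})
        if acc > best[1]:
            best = (j, acc)
    if best[0] is None:
        raise ValueError("no admissible J in the scanned range")
    return best[0], pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return (and optionally write) a report.

    The report echoes the configuration and seed, the selection outcome
    (mask, fitness history) and per-classifier pooled metrics, so a run
    can be reconstructed from its report alone.
    """
    records = _load_records(config.data)
    logger.info("loaded %d records", len(records))
    matrix = extract_feature_matrix(
        records, config.Q, config.r, config.J, config.entropy
    )
    logger.info("feature matrix: %s", matrix.values.shape)

    selector = config.selector.lower()
    selection: SelectionResult | None = None
    pvalues = None
    if selector == "none":
        mask = np.ones(matrix.n_features, dtype=np.uint8)
    elif selector == "kws":
        pvalues = kws_pvalues(matrix)
        mask = (pvalues < 0.05).astype(np.uint8)
        if mask.sum() == 0:
            raise RuntimeError("Kruskal-Wallis screening removed every feature")
    else:
        fitness_family = config.fitness_family or config.classifiers[0]
        fit_spec = ClassifierSpec(
            fitness_family,
            config.classifier_hyperparams.get(fitness_family, {}),
            config.seed,
        )
        ctx = make_wrapper_fitness(
            matrix, fit_spec, folds=config.fitness_folds, seed=config.seed
        )
        selection = run_selector(
            ctx,
            MetaheuristicConfig(
                method=selector,
                seed=config.seed,
                overrides=config.selector_overrides,
            ),
        )
        mask = selection.mask
        logger.info(
            "%s selected %d/%d features (fitness %.2f)",
            selection.method,
            selection.n_selected,
            matrix.n_features,
            selection.best_fitness,
        )

    selected = matrix.select(mask.astype(bool))
    results: dict[str, CVResult] = {}
    for family in config.classifiers:
        spec = ClassifierSpec(
            family, config.classifier_hyperparams.get(family, {}), config.seed
        )
        results[family] = cross_validate(
            spec, selected, folds=config.folds, seed=config.seed
        )

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "Q": config.Q,
            "r": config.r,
            "J": config.J,
            "epsilon": config.entropy.epsilon,
            "selector": selector,
            "fitness_family": config.fitness_family,
            "fitness_folds": config.fitness_folds,
            "folds": config.folds,
            "n_records": len(records),
        },
        "n_features_total": matrix.n_features,
        "n_features_selected": int(mask.sum()),
        "mask": [int(b) for b in mask],
        "selection": (
            selection.to_dict(matrix.feature_names) if selection else None
        ),
        "kws_pvalues": (
            {n: float(p) for n, p in zip(matrix.feature_names, pvalues)}
            if pvalues is not None
            else None
        ),
        "classifiers": {
            family: {
                "acc": res.metrics.acc,
                "sen": res.metrics.sen,
                "spe": res.metrics.spe,
                "counts": {
                    "tp": res.counts.tp,
                    "tn": res.counts.tn,
                    "fp": res.counts.fp,
                    "fn": res.counts.fn,
                },
                "fold_counts": [
                    {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                    for c in res.fold_counts
                ],
            }
            for family, res in results.items()
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        leaderboard = pd.DataFrame(
            [
                {
                    "classifier": family,
                    "selector": selector,
                    "n_features": int(mask.sum()),
                    "acc": res.metrics.acc,
                    "sen": res.metrics.sen,
                    "spe": res.metrics.spe,
                }
                for family, res in results.items()
            ]
        )
        leaderboard.to_csv(out / "leaderboard.csv", index=False)
        matrix.to_csv(out / "features.csv")
    return report
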