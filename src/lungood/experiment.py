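"""End-to-end evaluation: train encoder, fit the control density, score,
aggregate and report test AUC over repeated seeded runs.

Each run re-trains the encoder and the density model on a fresh
subject-level train/validation/test split. The density model sees only
representations of healthy-filtered patches from control subjects in the
training split, mirroring how the normal-appearing-lung distribution is
acquired; the contrastive pretext task itself trains on all training
subjects, labels unused. The aggregation strategy is selected once, by the
highest mean validation AUC over the runs, and the reported result is the
per-run test AUC of that strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregate import DEFAULT_STRATEGIES, aggregate, auc, select_aggregation
from .density import fit_gmm, fit_flow, score_representations, select_k_bic
from .encoder import EncoderConfig, TrainedEncoder, encode, train_encoder
from .preproc import (PatchGridSpec, extract_patch_grid, filter_healthy_patches,
                      normalize_intensities, subsample_patches)
from .types import CTVolumePair

__all__ = ["ExperimentResult", "RunArtifacts", "stratified_split",
           "run_experiment", "permutation_null_auc"]

MAX_PATCHES_PER_SUBJECT = 100


@dataclass
class RunArtifacts:
    """Fitted models and scores of one run, for inspection and map rendering."""

    encoder: TrainedEncoder
    density: object
    patch_scores: dict[str, list]          # subject_id -> list[AnomalyScore]
    test_subjects: list[str]
    val_subjects: list[str]
    train_subjects: list[str]


@dataclass
class ExperimentResult:
    per_run_aucs: list[float]
    strategy: str
    config_tag: str
    val_aucs: dict[str, list[float]] = field(default_factory=dict)
    artifacts: RunArtifacts | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_run_aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.per_run_aucs))


def stratified_split(labels: dict[str, str], fractions=(0.5, 0.2, 0.3),
                     seed: int = 0) -> dict[str, str]:
    """Subject-level stratified train/val/test split.

    Shuffles within each label class and cuts by the given fractions; every
    subject lands in exactly one split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for lab in sorted(set(labels.values())):
        sids = sorted(s for s, l in labels.items() if l == lab)
        rng.shuffle(sids)
        n = len(sids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for i, sid in enumerate(sids):
            assignment[sid] = ("train" if i < n_train
                               else "val" if i < n_train + n_val else "test")
    return assignment


def _check_disjoint(split: dict[str, str]) -> dict[str, list[str]]:
    groups = {"train": [], "val": [], "test": []}
    for sid, part in split.items():
        if part not in groups:
            raise ValueError(f"unknown split {part!r} for subject {sid}")
        groups[part].append(sid)
    for part, sids in groups.items():
        if len(set(sids)) != len(sids):
            raise ValueError(f"subject overlap within split {part}")
    return groups


def run_experiment(cohort: list[CTVolumePair], grid: PatchGridSpec,
                   encoder_cfg: EncoderConfig, n_runs: int = 3,
                   seeds: list[int] | None = None,
                   density_family: str = "gmm",
                   n_components: int | None = 2,
                   strategies=DEFAULT_STRATEGIES,
                   split_fractions=(0.5, 0.2, 0.3),
                   splits: dict[str, str] | None = None,
                   keep_artifacts: bool = False) -> ExperimentResult:
    """Run the full pipeline ``n_runs`` times and report test AUCs.

    ``n_components=None`` selects the mixture size by BIC;
    ``density_family="flow"`` uses the normalizing flow instead. A
    user-supplied ``splits`` mapping fixes the split across runs and is
    validated for overlap.
    """
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    labels = {p.subject_id: p.label for p in cohort}
    if len(labels) != len(cohort):
        raise ValueError("duplicate subject_ids in cohort")

    # patch extraction is split-independent: do it once
    patches_by_subject = {}
    for pair in cohort:
        patches, _report = extract_patch_grid(pair, grid)
        patches_by_subject[pair.subject_id] = patches

    val_aucs: dict[str, list[float]] = {s: [] for s in strategies}
    test_aucs: dict[str, list[float]] = {s: [] for s in strategies}
    artifacts = None

    for run, seed in enumerate(seeds):
        ss = np.random.SeedSequence(seed)
        sub_seeds = ss.generate_state(4 + len(cohort)).tolist()
        split = splits or stratified_split(labels, split_fractions,
                                           seed=sub_seeds[0] % 2**31)
        groups = _check_disjoint(split)
        if not groups["train"] or not groups["val"] or not groups["test"]:
            raise ValueError("each split must contain at least one subject")

        capped = {
            sid: subsample_patches(patches_by_subject[sid],
                                   MAX_PATCHES_PER_SUBJECT,
                                   seed=(sub_seeds[4 + i] + run) % 2**31)
            for i, sid in enumerate(sorted(labels))
        }

        train_pool = [p for sid in groups["train"] for p in capped[sid]]
        enc_cfg = EncoderConfig(**{**encoder_cfg.__dict__,
                                   "seed": sub_seeds[1] % 2**31})
        enc = train_encoder(train_pool, enc_cfg)

        control_pool = [
            p for sid in groups["train"] if labels[sid] == "control"
            for p in filter_healthy_patches(capped[sid])
        ]
        if not control_pool:
            raise ValueError("no healthy-filtered control patches to fit p(z)")
        Z = np.stack([r.z for r in encode(enc, control_pool)])
        if density_family == "gmm":
            if n_components is None:
                density = select_k_bic(Z, seed=sub_seeds[2] % 2**31)
            else:
                density = fit_gmm(Z, K=n_components, seed=sub_seeds[2] % 2**31)
        elif density_family == "flow":
            density = fit_flow(Z, seed=sub_seeds[2] % 2**31)
        else:
            raise ValueError(f"unknown density family {density_family!r}")

        patch_scores = {}
        for sid in groups["val"] + groups["test"]:
            reps = encode(enc, capped[sid])
            patch_scores[sid] = score_representations(density, reps)

        for strat in strategies:
            for part, store in (("val", val_aucs), ("test", test_aucs)):
                sids = groups[part]
                S = [aggregate([a.s for a in patch_scores[sid]], strat, sid).S
                     for sid in sids]
                store[strat].append(auc(S, [labels[sid] for sid in sids]))

        if keep_artifacts and run == len(seeds) - 1:
            artifacts = RunArtifacts(
                encoder=enc, density=density, patch_scores=patch_scores,
                test_subjects=groups["test"], val_subjects=groups["val"],
                train_subjects=groups["train"],
            )

    chosen = select_aggregation(strategies, val_aucs)
    tag = f"{grid.channels}-{int(round(grid.overlap_fraction * 100))}%"
    return ExperimentResult(per_run_aucs=test_aucs[chosen], strategy=chosen,
                            config_tag=tag, val_aucs=val_aucs,
                            artifacts=artifacts)


def permutation_null_auc(scores, labels, n_permutations: int = 20,
                         seed: int = 0) -> float:
    """Mean AUC after shuffling labels: a chance-level reference near 0.5."""
    rng = np.random.default_rng(seed)
    labels = list(labels)
    vals = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        vals.append(auc(scores, [labels[i] for i in perm]))
    return float(np.mean(vals))
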