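"""Semi-supervised curation of eluted-ligand immunopeptidome data.

Mass-spectrometry eluted-ligand (EL) experiments yield positive
peptides only; negatives are randomly sampled decoys, and peptides from
multi-allelic cell lines carry a whole candidate allele set rather than
the presenting allele.  The curation pipeline:

1. pre-trains a regression ensemble on binding-affinity (BA) data
   (log-affinity score targets);
2. deconvolves each multi-allele positive to the single candidate
   allele with the highest predicted score (ties broken
   lexicographically by allele name);
3. removes decoy negatives the regressor scores at or above a
   plausibility threshold (default: the score of 500 nM, ~0.4256),
   since a sampled "negative" predicted to bind is likely contamination;
4. merges the curated EL sets with the threshold-labelled BA set into
   one classification table, deduplicating exact repeats and resolving
   label conflicts in favour of the experimentally observed EL positive.

Steps 2-4 can be iterated (``rounds`` > 1), re-fitting the regressor on
the current curated table each round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import BINDER_SCORE, ic50_to_score, label_by_threshold
from .network import ModelConfig
from .train_eval import FoldEnsemble

logger = logging.getLogger(__name__)

#: Provenance tags.
PROV_BA = "BA"
PROV_SA = "ELS_SA"
PROV_MA = "ELS_MA"


def _candidate_list(value) -> list[str]:
    """Normalise an allele-set cell (list/tuple/comma-string) to a list."""
    if isinstance(value, str):
        return [a for a in value.split(",") if a]
    return list(value)


def deconvolve_multi_allele(els_ma: pd.DataFrame, model, pseudo_sequences: dict
                            ) -> pd.DataFrame:
    """Assign each positive multi-allele peptide its best-scoring allele.

    ``els_ma`` needs columns ``peptide``, ``alleles`` (candidate set),
    ``label``; only label-1 rows may be deconvolved.  Returns a copy
    with ``assigned_allele`` set and the candidate set collapsed to the
    winner.  The winner is the argmax of the model score over the
    candidates; exact ties go to the lexicographically smallest name.
    """
    if len(els_ma) == 0:
        out = els_ma.copy()
        out["assigned_allele"] = pd.Series(dtype=object)
        return out
    if (np.asarray(els_ma["label"]) != 1).any():
        raise ValueError("deconvolution applies to positive samples only")

    cand_lists = [sorted(_candidate_list(c)) for c in els_ma["alleles"]]
    for cands in cand_lists:
        if not cands:
            raise ValueError("empty candidate allele set")
        for a in cands:
            if a not in pseudo_sequences:
                raise KeyError(f"candidate allele {a!r} has no pseudo-sequence")

    flat_pep, flat_allele, owner = [], [], []
    for i, (pep, cands) in enumerate(zip(els_ma["peptide"], cand_lists)):
        for a in cands:
            flat_pep.append(pep)
            flat_allele.append(a)
            owner.append(i)
    scores = np.asarray(
        model.predict(pd.DataFrame({"peptide": flat_pep, "allele": flat_allele})),
        dtype=np.float64,
    )

    assigned = [None] * len(els_ma)
    best = np.full(len(els_ma), -np.inf)
    # candidates were sorted, so strict > keeps the lexicographically
    # smallest name on exact ties
    for s, a, i in zip(scores, flat_allele, owner):
        if s > best[i]:
            best[i] = s
            assigned[i] = a
    out = els_ma.copy()
    out["assigned_allele"] = assigned
    out["alleles"] = assigned
    return out


def filter_negatives(dataset: pd.DataFrame, model, score_threshold: float
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split decoy negatives into kept (score < threshold) and removed.

    Positives are never touched.  Single-allele rows are scored against
    their own allele; the report counts are exact.
    """
    if not np.isfinite(score_threshold) and score_threshold < 0:
        raise ValueError("threshold must be finite or +inf")
    dataset = dataset.reset_index(drop=True)
    is_neg = np.asarray(dataset["label"]) == 0
    neg = dataset[is_neg]
    if len(neg) == 0:
        report = {"n_negatives_in": 0, "n_negatives_removed": 0,
                  "score_threshold": float(score_threshold)}
        return dataset.copy(), dataset.iloc[0:0].copy(), report
    alleles = [_candidate_list(c)[0] for c in neg["alleles"]]
    scores = np.asarray(
        model.predict(pd.DataFrame({"peptide": list(neg["peptide"]),
                                    "allele": alleles})),
        dtype=np.float64,
    )
    remove = scores >= score_threshold
    removed_idx = neg.index[remove]
    removed = dataset.loc[removed_idx].copy()
    kept = dataset.drop(index=removed_idx).copy()
    report = {
        "n_negatives_in": int(is_neg.sum()),
        "n_negatives_removed": int(remove.sum()),
        "score_threshold": float(score_threshold),
    }
    return kept, removed, report


def merge_datasets(ba: pd.DataFrame, els_sa: pd.DataFrame,
                   els_ma_deconv: pd.DataFrame) -> pd.DataFrame:
    """Merge BA + curated EL sets into one classification table.

    Output columns: peptide, allele, label, provenance, fold.  Exact
    (peptide, allele, label) duplicates collapse with provenance union;
    a BA/EL label conflict for the same (peptide, allele) keeps the
    eluted-ligand positive and is logged.
    """
    frames = []
    if len(ba):
        ba = ba.copy()
        if "label" not in ba.columns:
            ba["label"] = label_by_threshold(np.asarray(ba["ic50_nM"], dtype=float))
        frames.append(pd.DataFrame({
            "peptide": ba["peptide"],
            "allele": ba["allele"],
            "label": np.asarray(ba["label"], dtype=np.int64),
            "provenance": PROV_BA,
            "fold": ba["fold"] if "fold" in ba.columns else -1,
        }))
    for df, prov in ((els_sa, PROV_SA), (els_ma_deconv, PROV_MA)):
        if len(df) == 0:
            continue
        alleles = [_candidate_list(c)[0] for c in df["alleles"]]
        frames.append(pd.DataFrame({
            "peptide": list(df["peptide"]),
            "allele": alleles,
            "label": np.asarray(df["label"], dtype=np.int64),
            "provenance": prov,
            "fold": df["fold"] if "fold" in df.columns else -1,
        }))
    if not frames:
        return pd.DataFrame(columns=["peptide", "allele", "label",
                                     "provenance", "fold"])
    merged = pd.concat(frames, ignore_index=True)

    def _collapse(group: pd.DataFrame) -> pd.Series:
        labels = set(group["label"])
        if len(labels) > 1:
            el_pos = group[(group["label"] == 1)
                           & (group["provenance"] != PROV_BA)]
            label = 1 if len(el_pos) else int(max(labels))
            logger.warning(
                "label conflict for %s; keeping label %d", group.name, label,
            )
            group = group[group["label"] == label]
        provs = sorted(set(group["provenance"]))
        folds = [f for f in group["fold"] if f >= 0]
        return pd.Series({
            "label": int(group["label"].iloc[0]),
            "provenance": ",".join(provs),
            "fold": folds[0] if folds else -1,
        })

    out = (merged.groupby(["peptide", "allele"], sort=False)
                 .apply(_collapse, include_groups=False)
                 .reset_index())
    out["label"] = out["label"].astype(np.int64)
    out["fold"] = out["fold"].astype(np.int64)
    return out


@dataclass
class CurationReport:
    """Audit trail of one curation run."""

    n_input: int = 0
    n_negatives_removed: int = 0
    n_ma_deconvolved: int = 0
    per_allele_assignments: dict = field(default_factory=dict)
    score_threshold: float = float(BINDER_SCORE)
    rounds: int = 1
    seed: int = 0
    n_output: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class CurationConfig:
    model_config: ModelConfig
    pseudo_sequences: dict
    score_threshold: float | None = None  # default: score of 500 nM
    rounds: int = 1
    n_folds: int = 5
    seed: int = 0
    refit_each_round: bool = True


def run_curation(ba: pd.DataFrame, els_sa: pd.DataFrame, els_ma: pd.DataFrame,
                 config: CurationConfig, model=None):
    """Full pipeline: pretrain -> deconvolve -> filter -> merge.

    A pre-fitted regression scorer may be injected via ``model`` to skip
    the pre-training step.  Returns ``(training_table, CurationReport,
    regression_model)``.
    """
    if len(ba) == 0:
        raise ValueError("BA dataset is empty; pre-training impossible")
    threshold = (float(BINDER_SCORE) if config.score_threshold is None
                 else float(config.score_threshold))
    from dataclasses import replace

    reg_cfg = replace(config.model_config, task="regression")
    ba = ba.reset_index(drop=True)
    if model is None:
        ensemble = FoldEnsemble(config=reg_cfg,
                                pseudo_sequences=config.pseudo_sequences,
                                n_folds=config.n_folds, seed=config.seed)
        ba_scores = ic50_to_score(np.asarray(ba["ic50_nM"], dtype=np.float64))
        ensemble.fit(ba[["peptide", "allele"]], ba_scores,
                     folds=ba["fold"] if "fold" in ba.columns else None)
    else:
        ensemble = model

    els_sa = els_sa.reset_index(drop=True)
    els_ma = els_ma.reset_index(drop=True)
    report = CurationReport(
        n_input=len(ba) + len(els_sa) + len(els_ma),
        score_threshold=threshold, rounds=config.rounds, seed=config.seed,
    )

    table = None
    for rnd in range(config.rounds):
        ma_pos = els_ma[els_ma["label"] == 1]
        ma_neg = els_ma[els_ma["label"] == 0]
        ma_deconv = deconvolve_multi_allele(ma_pos, ensemble,
                                            config.pseudo_sequences)
        report.n_ma_deconvolved = len(ma_deconv)
        counts = pd.Series(list(ma_deconv["assigned_allele"])).value_counts()
        report.per_allele_assignments = {str(k): int(v)
                                         for k, v in counts.items()}

        el_pool = pd.concat([els_sa, ma_deconv, ma_neg], ignore_index=True)
        kept, removed, frep = filter_negatives(el_pool, ensemble, threshold)
        report.n_negatives_removed = frep["n_negatives_removed"]

        if "assigned_allele" in kept.columns:
            ma_part = kept[kept["assigned_allele"].notna()]
            sa_part = kept[kept["assigned_allele"].isna()]
        else:
            ma_part, sa_part = kept.iloc[0:0], kept
        table = merge_datasets(ba, sa_part, ma_part)

        if rnd + 1 < config.rounds and config.refit_each_round:
            # refit the regressor on the curated table: log-affinity scores for
            # BA rows are unavailable post-merge, so binary labels serve
            # as pseudo-score targets on the same [0, 1] scale
            ensemble = FoldEnsemble(config=reg_cfg,
                                    pseudo_sequences=config.pseudo_sequences,
                                    n_folds=config.n_folds,
                                    seed=config.seed + rnd + 1)
            ensemble.fit(table[["peptide", "allele"]],
                         np.asarray(table["label"], dtype=np.float64),
                         folds=None)

    report.n_output = len(table)
    return table, report, ensemble
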