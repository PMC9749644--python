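"""Critical-SNP identification, Random-Forest scoring, gene prioritisation.

SNPs shared by multiple validated disease signatures are *critical* SNPs —
the canonical markers of a signature cluster.  They are scored with a
Random Forest under stratified five-fold cross-validation for how well
their genotypes predict the case/control split (Gini impurity importance),
and genes inherit the cumulative score of the critical SNPs assigned to
them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import GenotypeMatrix
from .mining import Signature

__all__ = [
    "CriticalSnpScore",
    "GenePriority",
    "find_critical_snps",
    "score_critical_snps",
    "prioritize_genes",
]


@dataclass(frozen=True)
class CriticalSnpScore:
    snp_id: str
    n_signatures: int
    rf_score: float  # mean Gini importance across folds
    cv_accuracy: float  # pooled out-of-fold accuracy (shared across SNPs)


@dataclass(frozen=True)
class GenePriority:
    gene_id: str
    cumulative_score: float
    snp_ids: tuple[str, ...]


def find_critical_snps(
    validated: list[Signature], critical_min: int = 2
) -> dict[str, int]:
    """SNPs appearing (any genotype state) in >= ``critical_min`` validated
    signatures; returns snp_id -> signature count."""
    if not validated:
        raise ValueError("no validated signatures")
    counts = Counter(snp for sig in validated for snp in set(sig.snp_ids))
    return {s: n for s, n in sorted(counts.items()) if n >= critical_min}


def score_critical_snps(
    gm: GenotypeMatrix,
    critical_snps,
    n_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> list[CriticalSnpScore]:
    """Stratified k-fold Random-Forest scoring of the critical-SNP panel.

    Genotypes are fed ordinally with missing kept as its own value (-1), so
    trees can split missingness into its own branch.  ``rf_score`` is the
    mean impurity-decrease importance across folds; ``cv_accuracy`` is the
    pooled out-of-fold accuracy of the panel as a whole.
    """
    snp_counts = dict(critical_snps) if isinstance(critical_snps, dict) else {
        s: 0 for s in critical_snps
    }
    snps = sorted(snp_counts)
    if not snps:
        raise ValueError("need at least one critical SNP")
    if gm.n_cases == 0 or gm.n_controls == 0:
        raise ValueError("both classes must be present")
    cols = [gm.snp_index(s) for s in snps]
    X = gm.genotypes[:, cols].astype(np.int16)
    y = gm.is_case.astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    importances = np.zeros((n_folds, len(snps)))
    correct = 0
    for fold, (train, test) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed + fold,
            n_jobs=1,
        )
        clf.fit(X[train], y[train])
        importances[fold] = clf.feature_importances_
        correct += int((clf.predict(X[test]) == y[test]).sum())
    mean_imp = importances.mean(axis=0)
    cv_acc = correct / len(y)
    return [
        CriticalSnpScore(s, snp_counts[s], float(mean_imp[i]), cv_acc)
        for i, s in enumerate(snps)
    ]


def prioritize_genes(
    scores: list[CriticalSnpScore], assignments: pd.DataFrame
) -> list[GenePriority]:
    """Rank genes by the cumulative RF score of their assigned critical SNPs.

    A SNP mapped to several genes contributes its full score to each (no
    apportionment); unassigned SNPs contribute nowhere.  Ties break by
    gene_id.
    """
    score_of = {s.snp_id: s.rf_score for s in scores}
    per_gene: dict[str, list[str]] = {}
    for _, row in assignments.iterrows():
        if row["snp_id"] in score_of:
            per_gene.setdefault(row["gene_id"], []).append(row["snp_id"])
    out = [
        GenePriority(
            gene_id=g,
            cumulative_score=float(sum(score_of[s] for s in set(snps))),
            snp_ids=tuple(sorted(set(snps))),
        )
        for g, snps in per_gene.items()
    ]
    out.sort(key=lambda gp: (-gp.cumulative_score, gp.gene_id))
    return out


def scores_to_tsv(scores: list[CriticalSnpScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tn_signatures\trf_score\tcv_accuracy\n")
        for s in sorted(scores, key=lambda x: -x.rf_score):
            fh.write(f"{s.snp_id}\t{s.n_signatures}\t{s.rf_score:.17g}\t{s.cv_accuracy:.17g}\n")
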