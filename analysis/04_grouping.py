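#!/usr/bin/env python
"""Classify and cluster the responses along the gap/NB1 ratio.

Takes the 3-5 ms band-power features from step 03 and
(a) trains a linear SVM on the ratio-rule labels with 10-fold
    cross-validation and ROC analysis,
(b) checks the cluster count by silhouette analysis (2-10 clusters,
    cosine distance),
(c) runs binary cosine k-means, maps the larger cluster to the
    suppressed group, and scores the match with a confusion matrix and
    its informedness.
Prints the headline metrics and writes them to JSON.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from abrgap import (
    cluster_to_group,
    confusion_and_informedness,
    kmeans_two,
    silhouette_optimal_k,
    svm_classify,
)
from abrgap.io import write_metrics

IN = Path("results/features.tsv")
OUT = Path("results/grouping_metrics.json")
SEED = 1


def main() -> None:
    features = pd.read_csv(IN, sep="\t", comment="#")
    labels = features["group"].tolist()

    report = svm_classify(features[["lfb", "mfb", "hfb"]].to_numpy(), labels, seed=SEED)
    print(f"SVM: accuracy {report.accuracy_pct:.1f}% "
          f"({report.cv_accuracy_pct:.1f}% cross-validated), "
          f"precision {report.precision_pct:.1f}% "
          f"({report.cv_precision_pct:.1f}% CV), AUC {report.auc:.3f}")

    X2 = features[["lfb", "hfb"]].to_numpy()
    k, scores = silhouette_optimal_k(X2, seed=SEED, return_scores=True)
    print(f"silhouette selects k = {k} "
          f"(scores: {', '.join(f'{kk}: {v:.3f}' for kk, v in scores.items())})")

    clusters = kmeans_two(X2, seed=SEED)
    predicted = cluster_to_group(clusters, X2)
    cm = confusion_and_informedness(predicted, labels)
    print(f"k-means vs ratio rule: TP={cm.tp} FN={cm.fn} TN={cm.tn} FP={cm.fp} -> "
          f"SE={cm.sensitivity:.3f} SP={cm.specificity:.3f} I={cm.informedness:.3f}")

    feat = features.assign(kmeans=[p.value for p in predicted])
    sup = [r for r, g in feat.groupby("ratio")
           if (g["kmeans"] == "suppressed").mean() > 0.5]
    boundary = max(sup) if sup else float("nan")
    print(f"largest grid ratio in the suppressed cluster: {boundary:g}")

    write_metrics(
        {
            "svm": {
                "accuracy_pct": report.accuracy_pct,
                "cv_accuracy_pct": report.cv_accuracy_pct,
                "precision_pct": report.precision_pct,
                "cv_precision_pct": report.cv_precision_pct,
                "auc": report.auc,
            },
            "silhouette_optimal_k": k,
            "silhouette_scores": {str(kk): v for kk, v in scores.items()},
            "kmeans_informedness": cm.informedness,
            "boundary_estimate": boundary,
        },
        OUT,
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
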