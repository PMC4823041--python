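"""Expression cohorts: container, tab-separated IO and elementary operations.

An :class:`ExpressionDataset` holds one cohort's log2-scale feature x sample
matrix together with a binary class label per sample (e.g. presence of the
t(4;14) translocation).  Matrices travel as plain TSV: first column
``feature_id``, header row of sample IDs; the companion annotation table has
columns ``sample_id``, ``class`` and optionally ``cohort``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
CLASS_LABELS = (POSITIVE, NEGATIVE)

#: feature kind tags
MIRNA = "miRNA"
GENE = "gene"
TF = "TF"
FEATURE_KINDS = (MIRNA, GENE, TF)


@dataclass
class ExpressionDataset:
    """One cohort's log2 expression matrix with per-sample class labels.

    Parameters
    ----------
    cohort_id : str
        Label of the cohort (e.g. ``"discovery96"``).
    features : list of str
        Ordered, unique feature identifiers (rows).
    samples : list of str
        Ordered sample identifiers (columns).
    values : ndarray, shape (n_features, n_samples)
        Log2-scale expression values.
    classes : list of str
        Per-sample binary label, ``"positive"`` or ``"negative"``.
    feature_kinds : dict, optional
        Maps feature ID to ``"miRNA"``, ``"gene"`` or ``"TF"``; defaults to
        ``"gene"`` for unlisted features.
    """

    cohort_id: str
    features: list[str]
    samples: list[str]
    values: np.ndarray
    classes: list[str]
    feature_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        seen: set[str] = set()
        for f in self.features:
            if f in seen:
                raise ValueError(f"duplicate feature ID: {f!r}")
            seen.add(f)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if len(self.classes) != len(self.samples):
            raise ValueError("one class label required per sample")
        bad = sorted({c for c in self.classes if c not in CLASS_LABELS})
        if bad:
            raise ValueError(
                f"unknown class labels {bad}; expected one of {CLASS_LABELS}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        self._index = {f: i for i, f in enumerate(self.features)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def class_mask(self) -> np.ndarray:
        """Boolean mask of positive-class samples."""
        return np.array([c == POSITIVE for c in self.classes])

    def row(self, feature: str) -> np.ndarray:
        try:
            return self.values[self._index[feature]]
        except KeyError:
            raise KeyError(f"feature {feature!r} not in cohort "
                           f"{self.cohort_id!r}") from None

    def __contains__(self, feature: str) -> bool:
        return feature in self._index

    def kind_of(self, feature: str) -> str:
        return self.feature_kinds.get(feature, GENE)

    def subset_features(self, keep: Sequence[str]) -> "ExpressionDataset":
        """Return a dataset restricted to ``keep``, preserving row order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.features) if f in keep_set]
        feats = [self.features[i] for i in idx]
        return ExpressionDataset(
            cohort_id=self.cohort_id,
            features=feats,
            samples=list(self.samples),
            values=self.values[idx],
            classes=list(self.classes),
            feature_kinds={f: self.feature_kinds[f]
                           for f in feats if f in self.feature_kinds},
        )

    def require_min_class_size(self, n_min: int = 3) -> None:
        mask = self.class_mask
        n_pos, n_neg = int(mask.sum()), int((~mask).sum())
        if n_pos < n_min or n_neg < n_min:
            raise ValueError(
                f"cohort {self.cohort_id!r} needs >= {n_min} samples per "
                f"class (got {n_pos} positive, {n_neg} negative)"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features,
                            columns=self.samples)


# -- IO --------------------------------------------------------------------

def load_expression(path, annotation_path, cohort_id: str | None = None,
                    feature_kinds: dict[str, str] | None = None,
                    ) -> ExpressionDataset:
    """Read a TSV expression matrix plus its sample-annotation table.

    Samples present in the matrix but absent from the annotation are
    rejected; annotation rows for unknown samples are ignored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_filter=False,
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature ID in {path}: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in ann.columns:
            raise ValueError(f"annotation {annotation_path} lacks column "
                             f"{col!r}")
    class_of = dict(zip(ann["sample_id"], ann["class"]))
    samples = [str(s) for s in df.columns]
    missing = [s for s in samples if s not in class_of]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    if cohort_id is None:
        if "cohort" in ann.columns and ann["cohort"].notna().any():
            cohort_id = str(ann["cohort"].dropna().iloc[0])
        else:
            cohort_id = Path(path).stem
    return ExpressionDataset(
        cohort_id=cohort_id,
        features=[str(f) for f in df.index],
        samples=samples,
        values=values,
        classes=[class_of[s] for s in samples],
        feature_kinds=dict(feature_kinds or {}),
    )


def write_expression(ds: ExpressionDataset, path, annotation_path=None,
                     ) -> None:
    """Write a dataset back to TSV (matrix + optional annotation table)."""
    out = ds.to_frame()
    out.index.name = "feature_id"
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, sep="\t", float_format="%.17g")
    if annotation_path is not None:
        ann = pd.DataFrame({
            "sample_id": ds.samples,
            "class": ds.classes,
            "cohort": ds.cohort_id,
        })
        ann.to_csv(annotation_path, sep="\t", index=False)


# -- elementary operations -------------------------------------------------

def coefficient_of_variation(ds: ExpressionDataset) -> pd.Series:
    """Per-feature CV (sd/mean) computed on linear-scale values ``2**x``.

    Working on the linear scale keeps the CV positive and well defined;
    for log-normal intensities it depends only on the log-scale spread.
    """
    linear = np.exp2(ds.values)
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=0)
    cv = np.divide(sd, mean, out=np.full_like(mean, np.nan),
                   where=mean != 0)
    return pd.Series(cv, index=ds.features, name="cv")


def filter_by_cv(ds: ExpressionDataset, keep_fraction: float,
                 ) -> ExpressionDataset:
    """Retain the ``ceil(keep_fraction * n)`` features with largest CV.

    Exact CV ties break lexicographically by feature ID; feature order is
    preserved among survivors.  Features with zero linear-scale mean are
    excluded from the ranking with a warning.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return ds
    cv = coefficient_of_variation(ds)
    undefined = cv.index[cv.isna()].tolist()
    if undefined:
        logger.warning("%d features with zero mean excluded from CV "
                       "ranking: %s", len(undefined), undefined[:5])
    ranked = sorted(
        ((f, c) for f, c in cv.items() if not math.isnan(c)),
        key=lambda fc: (-fc[1], fc[0]),
    )
    n_keep = math.ceil(keep_fraction * ds.n_features)
    keep = {f for f, _ in ranked[:n_keep]}
    return ds.subset_features([f for f in ds.features if f in keep])


def class_log2ratio(ds: ExpressionDataset, feature: str) -> float:
    """Difference of class-mean log2 expression (positive minus negative)."""
    x = ds.row(feature)
    mask = ds.class_mask
    if not mask.any() or mask.all():
        raise ValueError(f"cohort {ds.cohort_id!r} lacks one of the two "
                         "classes")
    return float(x[mask].mean() - x[~mask].mean())


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-cohort differential-expression annotation of a network node."""

    node: str
    kind: str
    log2ratio: float
    cohort_id: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2ratio):
            raise ValueError(f"non-finite log2ratio for {self.node!r}")


def annotate_nodes(ds: ExpressionDataset, nodes: Iterable[str],
                   ) -> dict[str, NodeAnnotation]:
    """Compute log2ratio annotations for every node present in ``ds``."""
    out: dict[str, NodeAnnotation] = {}
    for node in nodes:
        if node not in ds:
            continue
        out[node] = NodeAnnotation(
            node=node, kind=ds.kind_of(node),
            log2ratio=class_log2ratio(ds, node), cohort_id=ds.cohort_id,
        )
    return out
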