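"""Box–Jenkins moving-average transform: condition-modified descriptors.

A multi-tasking QSAR model must see both structure and experimental
context.  The Box–Jenkins moving-average approach achieves this by
replacing each descriptor D with its deviation from the mean of D over
all modeling-set datapoints sharing a condition-field category:

    ΔD(d, f) = D(compound) − mean{ D(c') : record c' has f = c }

yielding one modified column per (descriptor, condition field) pair.  The
per-category means are fitted on the modeling set only — the external set
never contributes, which is the leakage boundary of the workflow — and
are persisted inside the model bundle so unseen compounds can be screened
self-contained.

``average_over`` selects whether category means are taken over all
modeling-set records of the category (default) or over the positive-class
records only; both variants appear in multi-tasking QSAR practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConditionMeans", "fit_condition_means", "transform", "modified_column"]


def modified_column(descriptor: str, field: str) -> str:
    """Column name of a modified descriptor: ``descriptor|field``."""
    return f"{descriptor}|{field}"


@dataclass
class ConditionMeans:
    """Per-(descriptor, field, category) means of the modeling set.

    ``means[field][category]`` is a vector over ``descriptors``;
    ``counts[field][category]`` the number of contributing records
    (always >= 1: categories unseen in the modeling set are absent).
    """

    fields: tuple
    descriptors: tuple
    means: dict
    counts: dict
    average_over: str = "all"

    def to_dict(self) -> dict:
        return {
            "fields": list(self.fields),
            "descriptors": list(self.descriptors),
            "average_over": self.average_over,
            "entries": [
                {
                    "field": f,
                    "category": cat,
                    "count": self.counts[f][cat],
                    "mean": [float(x) for x in self.means[f][cat]],
                }
                for f in self.fields
                for cat in self.means[f]
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConditionMeans":
        fields = tuple(payload["fields"])
        descriptors = tuple(payload["descriptors"])
        means: dict = {f: {} for f in fields}
        counts: dict = {f: {} for f in fields}
        for entry in payload["entries"]:
            f = entry["field"]
            cat = entry["category"]
            means[f][cat] = np.asarray(entry["mean"], dtype=float)
            counts[f][cat] = int(entry["count"])
        return cls(fields, descriptors, means, counts, payload.get("average_over", "all"))


def fit_condition_means(
    records,
    descriptor_matrix: pd.DataFrame,
    fields=None,
    average_over: str = "all",
) -> ConditionMeans:
    """Fit per-category descriptor means on the modeling set.

    Every record contributes its compound's descriptor row once per
    condition field — a compound measured under three buffers weighs three
    times in no buffer category but once in each of its three.  With
    ``average_over="positives"`` only records with class_label == 1
    contribute (their categories must still cover the data to transform).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to fit condition means on")
    if fields is None:
        fields = records[0].condition.fields
    fields = tuple(fields)
    if average_over not in ("all", "positives"):
        raise ValueError(f"unknown average_over {average_over!r}")

    descriptors = tuple(descriptor_matrix.columns)
    X = descriptor_matrix.to_numpy(dtype=float)
    row_of = {cid: i for i, cid in enumerate(descriptor_matrix.index)}

    means: dict = {f: {} for f in fields}
    counts: dict = {f: {} for f in fields}
    sums: dict = {f: {} for f in fields}
    for r in records:
        if average_over == "positives" and r.class_label != 1:
            continue
        try:
            xi = X[row_of[r.compound_id]]
        except KeyError:
            raise ValueError(f"no descriptor row for compound {r.compound_id}") from None
        for f in fields:
            cat = r.condition[f]
            if cat not in sums[f]:
                sums[f][cat] = np.zeros(len(descriptors))
                counts[f][cat] = 0
            sums[f][cat] += xi
            counts[f][cat] += 1
    for f in fields:
        if not sums[f]:
            raise ValueError(f"no records contribute to field {f!r}")
        for cat, s in sums[f].items():
            means[f][cat] = s / counts[f][cat]
    return ConditionMeans(fields, descriptors, means, counts, average_over)


def transform(
    records,
    descriptor_matrix: pd.DataFrame,
    means: ConditionMeans,
    on_unseen: str = "error",
) -> pd.DataFrame:
    """Modified-descriptor matrix: rows = records, columns = (d, f) pairs.

    ``on_unseen`` controls records whose condition category has no stored
    mean: ``"error"`` (default, strict) raises naming field and category;
    ``"skip"`` drops the record and lists it in ``frame.attrs["skipped"]``.
    """
    if on_unseen not in ("error", "skip"):
        raise ValueError(f"unknown on_unseen policy {on_unseen!r}")
    records = list(records)
    descriptors = list(means.descriptors)
    missing_cols = [d for d in descriptors if d not in descriptor_matrix.columns]
    if missing_cols:
        raise ValueError(f"descriptor matrix lacks fitted columns: {missing_cols[:5]}")
    sub = descriptor_matrix[descriptors]
    X = sub.to_numpy(dtype=float)
    row_of = {cid: i for i, cid in enumerate(sub.index)}

    columns = [modified_column(d, f) for f in means.fields for d in descriptors]
    out_rows, index, skipped = [], [], []
    for r in records:
        xi = X[row_of[r.compound_id]]
        deltas = []
        unseen = None
        for f in means.fields:
            cat = r.condition[f]
            mu = means.means[f].get(cat)
            if mu is None:
                unseen = (f, cat)
                break
            deltas.append(xi - mu)
        if unseen is not None:
            if on_unseen == "error":
                raise KeyError(
                    f"record {r.record_id}: no condition mean for field "
                    f"{unseen[0]!r} category {unseen[1]!r}"
                )
            skipped.append(r.record_id)
            continue
        out_rows.append(np.concatenate(deltas))
        index.append(r.record_id)
    frame = pd.DataFrame(out_rows, index=index, columns=columns, dtype=float)
    frame.attrs["skipped"] = skipped
    frame.attrs["fields"] = list(means.fields)
    frame.attrs["backend"] = descriptor_matrix.attrs.get("backend")
    return frame
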