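"""Comparative-Ct (delta-delta-Ct) relative quantification of qPCR data.

For each sample, replicate Ct values are averaged per gene (the
run-in-duplicate design); the target gene's mean Ct is normalized against
the housekeeping gene (Hprt by default) to give

    dCt  = mean Ct(target) - mean Ct(housekeeping),
    ddCt = dCt - mean dCt of the reference group,
    fold = 2^(-ddCt),

assuming the comparative-Ct doubling-per-cycle amplification efficiency.
Referencing to the reference-group *mean* dCt makes the geometric mean of
the reference group's folds exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .timeseries_io import QpcrRecord, ValidationError

__all__ = ["FoldChange", "relative_expression"]


@dataclass
class FoldChange:
    """Relative expression of one sample's target gene.

    ``delta_ct`` is the housekeeping-normalized Ct (cycles); ``fold`` is the
    expression relative to the reference-group mean, always > 0.
    """

    sample_id: str
    group: str
    gene: str
    delta_ct: float
    fold: float


def relative_expression(
    records: Iterable[QpcrRecord],
    gene: str,
    housekeeping: str = "Hprt",
    reference_group: str = "control",
) -> list[FoldChange]:
    """Comparative-Ct fold changes for ``gene``, one per sample.

    Raises :class:`ValidationError` naming the sample if any sample with a
    target measurement lacks a housekeeping measurement, and if the reference
    group contributes no samples.
    """
    target: dict[str, QpcrRecord] = {}
    hk: dict[str, QpcrRecord] = {}
    for r in records:
        if r.gene.lower() == gene.lower():
            target[r.sample_id] = r
        elif r.gene.lower() == housekeeping.lower():
            hk[r.sample_id] = r
    if not target:
        raise ValidationError(f"no records for target gene {gene!r}")

    delta_ct = {}
    for sample, rec in target.items():
        if sample not in hk:
            raise ValidationError(
                f"sample {sample!r} has no housekeeping ({housekeeping!r}) Ct"
            )
        delta_ct[sample] = rec.mean_ct - hk[sample].mean_ct

    ref = [delta_ct[s] for s, rec in target.items() if rec.group == reference_group]
    if not ref:
        raise ValidationError(f"reference group {reference_group!r} has no samples")
    ref_mean = float(np.mean(ref))

    return [
        FoldChange(
            sample_id=sample,
            group=rec.group,
            gene=rec.gene,
            delta_ct=delta_ct[sample],
            fold=float(2.0 ** -(delta_ct[sample] - ref_mean)),
        )
        for sample, rec in target.items()
    ]
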