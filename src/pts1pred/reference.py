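"""Published benchmark operating points for the two reference models.

The original plant PTS1 predictor was released in two flavours trained on
curated sets: an Arabidopsis-only model (90 positives, 176 negatives) and an
all-plants model (99 positives; 196 negatives reported in the data-collection
summary, but 198 in the candidate accounting — and only with 198 do the
published accuracy and MCC cells reconstruct exactly from integer confusion
counts, so 198 is taken as the count the table was computed with).

For each decision cut-off the publication reports sensitivity, specificity,
accuracy and MCC of 5-fold cross-validation. These numbers are shipped here
as benchmark inputs: :func:`pts1pred.evaluation.reconstruct_confusion`
recovers the integer confusion behind each column, from which the metric
formulas can be re-derived and checked against the printed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

CUTOFFS: tuple[float, ...] = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)


@dataclass(frozen=True)
class PublishedSweep:
    """One model's published cut-off sweep (None marks an N.A. cell)."""

    name: str
    n_pos: int
    n_neg: int
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    accuracy: tuple[float, ...]
    mcc: tuple[float | None, ...]

    def column(self, cutoff: float) -> dict[str, float | None]:
        i = CUTOFFS.index(cutoff)
        return {
            "sensitivity": self.sensitivity[i],
            "specificity": self.specificity[i],
            "accuracy": self.accuracy[i],
            "mcc": self.mcc[i],
        }


ARABIDOPSIS = PublishedSweep(
    name="arabidopsis",
    n_pos=90,
    n_neg=176,
    sensitivity=(1.0, 0.978, 0.956, 0.944, 0.944, 0.833, 0.6),
    specificity=(0.006, 0.551, 0.875, 0.875, 0.898, 0.987, 0.994),
    accuracy=(0.342, 0.695, 0.902, 0.898, 0.914, 0.936, 0.861),
    mcc=(0.044, 0.518, 0.800, 0.791, 0.818, 0.858, 0.694),
)

ALL_PLANTS = PublishedSweep(
    name="all_plants",
    n_pos=99,
    n_neg=198,  # the count the published table is consistent with; see module docstring
    sensitivity=(1.0, 0.990, 0.949, 0.939, 0.929, 0.808, 0.566),
    specificity=(0.0, 0.606, 0.869, 0.874, 0.894, 0.985, 0.995),
    accuracy=(0.333, 0.734, 0.896, 0.896, 0.906, 0.926, 0.852),
    mcc=(None, 0.572, 0.786, 0.783, 0.799, 0.833, 0.671),
)

#: Negative count reported in the all-plants data-collection summary; kept
#: for dataset-sizing (the generator's all-plants configuration uses it).
ALL_PLANTS_REPORTED_N_NEG = 196

SWEEPS: dict[str, PublishedSweep] = {
    "arabidopsis": ARABIDOPSIS,
    "all_plants": ALL_PLANTS,
}

#: Headline independent-comparison numbers for the all-plants model
#: (sensitivity/specificity on its own curated set).
ALL_PLANTS_HEADLINE = {"sensitivity": 0.929, "specificity": 0.894}
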