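"""Reference benchmark figures bundled for consistency checks.

These are the published evaluation numbers for the semantic-type relation
classifier with per-class threshold calibration ("model") and for the
rule-based triple extractor it complements ("extractor"), on the
gold-standard test split, plus the headline counts of the large-scale
predication-expansion assessment.  They serve as *inputs* to arithmetic
self-consistency checks (micro-F1 as the harmonic mean of the printed
micro precision/recall, macro-F1 as the mean of the printed per-class F1
values, the expansion estimate) — the package never tunes anything toward
them.
"""

from __future__ import annotations

from .schema import POSITIVE_LABELS, RelationLabel

__all__ = [
    "MODEL_PER_CLASS",
    "EXTRACTOR_PER_CLASS",
    "AGGREGATES",
    "LARGE_SCALE",
    "DATASET_SIZES",
]

# label -> (precision, recall, f1, calibrated threshold)
MODEL_PER_CLASS: dict[RelationLabel, tuple[float, float, float, float]] = {
    RelationLabel.administered_to: (0.70, 0.64, 0.67, 0.70),
    RelationLabel.affects: (0.64, 0.59, 0.62, 0.79),
    RelationLabel.associated_with: (0.48, 1.00, 0.65, 0.85),
    RelationLabel.augments: (0.55, 0.50, 0.52, 0.76),
    RelationLabel.causes: (0.69, 0.84, 0.76, 0.80),
    RelationLabel.coexists_with: (0.31, 0.63, 0.42, 0.50),
    RelationLabel.compared_with: (0.40, 0.50, 0.44, 0.55),
    RelationLabel.diagnoses: (0.69, 0.56, 0.62, 0.83),
    RelationLabel.disrupts: (0.44, 0.67, 0.53, 0.81),
    RelationLabel.inhibits: (0.47, 0.58, 0.52, 0.79),
    RelationLabel.interacts_with: (0.48, 0.91, 0.63, 0.50),
    RelationLabel.isa: (0.65, 0.49, 0.56, 0.74),
    RelationLabel.location_of: (0.60, 1.00, 0.75, 0.76),
    RelationLabel.part_of: (0.52, 1.00, 0.68, 0.76),
    RelationLabel.precedes: (1.00, 0.46, 0.63, 0.82),
    RelationLabel.predisposes: (0.56, 0.91, 0.69, 0.50),
    RelationLabel.prevents: (0.57, 1.00, 0.72, 0.67),
    RelationLabel.process_of: (0.86, 0.95, 0.90, 0.68),
    RelationLabel.produces: (0.42, 0.33, 0.37, 0.50),
    RelationLabel.stimulates: (0.48, 0.63, 0.54, 0.51),
    RelationLabel.treats: (0.71, 0.70, 0.70, 0.50),
    RelationLabel.uses: (0.62, 0.78, 0.69, 0.70),
}

# label -> (precision, recall, f1)
EXTRACTOR_PER_CLASS: dict[RelationLabel, tuple[float, float, float]] = {
    RelationLabel.administered_to: (0.40, 0.09, 0.15),
    RelationLabel.affects: (0.32, 0.09, 0.14),
    RelationLabel.associated_with: (0.38, 0.25, 0.30),
    RelationLabel.augments: (0.57, 0.33, 0.42),
    RelationLabel.causes: (0.77, 0.47, 0.58),
    RelationLabel.coexists_with: (0.19, 0.29, 0.23),
    RelationLabel.compared_with: (0.57, 0.50, 0.53),
    RelationLabel.diagnoses: (0.67, 0.25, 0.36),
    RelationLabel.disrupts: (0.40, 0.17, 0.24),
    RelationLabel.inhibits: (0.40, 0.17, 0.24),
    RelationLabel.interacts_with: (0.30, 0.21, 0.25),
    RelationLabel.isa: (0.80, 0.27, 0.41),
    RelationLabel.location_of: (0.52, 0.37, 0.43),
    RelationLabel.part_of: (0.76, 0.31, 0.44),
    RelationLabel.precedes: (1.00, 0.38, 0.56),
    RelationLabel.predisposes: (1.00, 0.18, 0.31),
    RelationLabel.prevents: (1.00, 0.46, 0.63),
    RelationLabel.process_of: (0.82, 0.66, 0.74),
    RelationLabel.produces: (0.38, 0.20, 0.26),
    RelationLabel.stimulates: (0.50, 0.44, 0.47),
    RelationLabel.treats: (0.55, 0.35, 0.43),
    RelationLabel.uses: (0.56, 0.37, 0.44),
}

assert set(MODEL_PER_CLASS) == set(POSITIVE_LABELS)
assert set(EXTRACTOR_PER_CLASS) == set(POSITIVE_LABELS)

#: headline aggregates: (precision, recall, f1), null label excluded
AGGREGATES = {
    "model_micro": (0.62, 0.81, 0.70),
    "model_macro": (0.58, 0.71, 0.62),
    "model_nothreshold_micro": (0.57, 0.84, 0.68),
    "extractor_micro": (0.61, 0.37, 0.46),
    "extractor_macro": (0.58, 0.31, 0.39),
}

#: large-scale expansion assessment over the 12K-abstract sample
LARGE_SCALE = {
    "model_total": 103_999,
    "new_not_in_store": 77_541,
    "extractor_only": 25_242,
    "store_total": 51_564,
    "review_sample": 506,
    "review_per_category": 23,
    "review_accuracy": 0.67,
    "estimated_increase": 51_952,
}

DATASET_SIZES = {"train": 8_255, "val": 761, "test": 3_841, "total": 12_857}
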