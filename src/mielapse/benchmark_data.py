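"""Published site-level summaries of the greenhouse pollinator benchmark.

The public time-lapse insect benchmark (https://vision.eng.au.dk/mie)
reports, per camera site, the number of annotated insects and recorded
images, and the detection metrics of CNN detectors evaluated on plain
colour images versus motion-enhanced images.  Those published summary
rows are embedded here so the evaluation code's aggregation arithmetic
can be checked against them without downloading the 100k-image dataset.

All values are printed to the precision of the published tables.
"""

from __future__ import annotations

from .evaluation import SiteMetrics

# Test benchmark: per-site annotated insects and recorded images over one
# week of 30 s time-lapse recording (seven sites, three plant species).
TEST_SITE_COUNTS: dict[str, tuple[int, int]] = {
    # site: (insects, images)
    "S1-0": (170, 14092),
    "S1-1": (333, 15120),
    "S2-0": (322, 14066),
    "S2-1": (411, 14011),
    "S3-0": (2100, 15120),
    "S4-0": (2319, 15120),
    "S4-1": (701, 15120),
}

# Training/validation source recordings: per (camera, week) annotated
# insects and insect-free background images.
TRAIN_SOURCE_COUNTS: dict[tuple[str, int], tuple[int, int]] = {
    # (camera, week): (insects, background images)
    ("S1-1", 26): (1079, 340),
    ("S1-1", 27): (21, 312),
    ("S1-0", 29): (395, 143),
    ("S1-0", 30): (648, 115),
    ("S2-1", 27): (186, 136),
    ("S3-0", 29): (120, 308),
    ("S4-0", 28): (154, 533),
    ("S4-0", 30): (20, 468),
    ("S4-1", 28): (108, 77),
    ("S4-1", 29): (83, 93),
}

# Final training/validation split: (insects, images, background images).
FINAL_SPLIT_COUNTS: dict[str, tuple[int, int, int]] = {
    "train": (2499, 3783, 1953),
    "validate": (568, 946, 508),
}

# Per-site recall/precision/F1 of the two-stage CNN detector evaluated on
# colour vs motion-enhanced images (averages over five trained models).
TWO_STAGE_SITE_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    # site: variant -> (recall, precision, f1)
    "S1-0": {"color": (0.051, 0.032, 0.037), "motion": (0.262, 0.758, 0.385)},
    "S1-1": {"color": (0.141, 0.112, 0.112), "motion": (0.413, 0.488, 0.435)},
    "S2-0": {"color": (0.305, 0.250, 0.274), "motion": (0.529, 0.650, 0.576)},
    "S2-1": {"color": (0.355, 0.398, 0.374), "motion": (0.496, 0.599, 0.532)},
    "S3-0": {"color": (0.404, 0.538, 0.459), "motion": (0.487, 0.840, 0.612)},
    "S4-0": {"color": (0.178, 0.539, 0.267), "motion": (0.365, 0.891, 0.515)},
    "S4-1": {"color": (0.496, 0.262, 0.337), "motion": (0.585, 0.634, 0.603)},
}

# Same structure for the one-stage CNN detector.
ONE_STAGE_SITE_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    "S1-0": {"color": (0.028, 0.019, 0.017), "motion": (0.284, 0.693, 0.389)},
    "S1-1": {"color": (0.126, 0.210, 0.147), "motion": (0.502, 0.437, 0.463)},
    "S2-0": {"color": (0.288, 0.619, 0.376), "motion": (0.630, 0.674, 0.643)},
    "S2-1": {"color": (0.335, 0.784, 0.461), "motion": (0.635, 0.621, 0.618)},
    "S3-0": {"color": (0.442, 0.890, 0.587), "motion": (0.694, 0.879, 0.772)},
    "S4-0": {"color": (0.368, 0.890, 0.517), "motion": (0.665, 0.865, 0.747)},
    "S4-1": {"color": (0.486, 0.917, 0.634), "motion": (0.733, 0.727, 0.727)},
}


def site_metrics(table: dict[str, dict[str, tuple[float, float, float]]],
                 variant: str) -> list[SiteMetrics]:
    """Published per-site metric rows as SiteMetrics (no raw counts)."""
    return [
        SiteMetrics(site_id=site, recall=r, precision=p, f1=f)
        for site, variants in table.items()
        for r, p, f in [variants[variant]]
    ]
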