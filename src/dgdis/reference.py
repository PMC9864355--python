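"""Published worked-example probabilities for the default configuration.

These are the example tables from the model's original publication:
fictitious patients identified by (TPG, CO_TD) with their printed PVR and
disagreement probability (percent), under bias 0 L/min, 1.96·SD 2 L/min
and CO limits 1.3–10.2 L/min.  They are used only for comparison reports
(``dgdis table --compare``): several printed cells — notably at low CO —
deviate from the closed-form evaluation of the model's own formulas by up
to ~10 percentage points, and the comparison report surfaces those
deviations rather than reproducing them.
"""

from __future__ import annotations

#: (tpg, co_td, printed PVR_TD, printed DgDis− percent) — unclassified PH by TD.
PUBLISHED_DGDIS_MINUS: tuple[tuple[float, float, float, float], ...] = (
    (6, 3.5, 1.7, 30.0),
    (7, 4, 1.75, 29.4),
    (7, 5, 1.4, 6.9),
    (8, 5, 1.6, 16.2),
    (8, 6, 1.3, 2.5),
    (9, 5, 1.8, 31.1),
    (9, 6, 1.5, 7.1),
    (10, 6, 1.7, 15.4),
    (10, 7, 1.4, 2.5),
    (11, 6, 1.8, 31.2),
    (11, 7, 1.6, 7.07),
)

#: (tpg, co_td, printed PVR_TD, printed DgDis+ percent) — precapillary PH by TD.
PUBLISHED_DGDIS_PLUS: tuple[tuple[float, float, float, float], ...] = (
    (6, 2.5, 2.4, 45.4),
    (7, 2.5, 2.8, 23.8),
    (7, 3, 2.3, 37.3),
    (8, 3, 2.7, 19.6),
    (8, 3.5, 2.3, 33.6),
    (9, 3, 3.0, 8.5),
    (9, 4, 2.3, 32.0),
    (10, 3, 3.3, 3.0),
    (10, 4, 2.5, 16.8),
    (11, 4, 2.75, 7.3),
    (11, 5, 2.2, 31.3),
)
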