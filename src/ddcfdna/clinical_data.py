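"""Bundled clinical validation series.

dd-cfDNA time courses (percent, days 0–28 after kidney transplantation) for
three donor–recipient relatedness types, as published for this workflow's
clinical validation: the direct genotype-based reference value alongside the
clustering estimates computed with and without pre-transplant data. These
are the inputs for the concordance (CCC) evaluation between the direct and
clustering-based methods.

Values are percentages as printed in the source report; ``PUBLISHED_CCC``
holds the concordance coefficients reported there (``None`` where the
coefficient was declared not-calculable because too few time points survive
the ≥10% exclusion applied in reference-free mode).
"""

from __future__ import annotations

DAYS_AFTER_TRANSPLANT = (0, 1, 3, 5, 7, 14, 28)

#: percent dd-cfDNA per relatedness: direct method, clustering with pre, without pre
CLINICAL_SERIES: dict[str, dict[str, tuple[float, ...]]] = {
    "unrelated": {
        "direct": (0.0, 27.4, 5.7, 1.5, 1.6, 0.5, 0.4),
        "clustering_with_pre": (0.0, 30.6, 5.6, 2.7, 2.0, 1.7, 1.6),
        "clustering_without_pre": (0.9, 6.4, 6.0, 2.5, 1.8, 1.1, 1.2),
    },
    "sibling": {
        "direct": (0.0, 27.9, 8.8, 3.1, 2.2, 1.1, 1.2),
        "clustering_with_pre": (0.0, 26.3, 9.0, 4.6, 2.3, 2.1, 2.8),
        "clustering_without_pre": (0.6, 2.7, 7.8, 3.6, 2.3, 1.6, 2.1),
    },
    "parent_child": {
        "direct": (0.0, 17.0, 35.5, 12.1, 12.0, 0.9, -0.7),
        "clustering_with_pre": (0.0, 17.1, 35.1, 12.2, 13.1, 3.5, 4.1),
        "clustering_without_pre": (0.5, 6.9, 0.3, 5.6, 6.0, 1.7, 3.1),
    },
}

#: published concordance coefficients (direct vs clustering), to 4 decimals
PUBLISHED_CCC: dict[str, dict[str, float | None]] = {
    "unrelated": {"with_pre": 0.9887, "without_pre": 0.9316},
    "sibling": {"with_pre": 0.9923, "without_pre": 0.9675},
    "parent_child": {"with_pre": 0.9831, "without_pre": None},
}

#: reference-free estimates lose accuracy above this level (percent)
EXCLUSION_THRESHOLD_PERCENT = 10.0
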