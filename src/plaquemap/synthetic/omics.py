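"""Synthetic analyte/expression experiments with planted effects.

Emulates the design of the sorted-microglia studies: two genotype groups
(wild type vs homozygous knock-in) balanced over sex and take-down-day
batches, one subject per sample, optional methoxy-X04 status. Log2
abundances are baseline + genotype effect + batch + sex offsets +
Gaussian noise; missingness is applied per feature, completely at random,
at 1 - detection_rate. Peak areas and internal-standard areas are
constructed so that internal-standard normalization recovers the log2
abundances exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from plaquemap.synthetic.truth import OmicsTruth

STANDARD_AREA = 1.0e4


def random_omics_truth(
    seed: int,
    n_features: int = 200,
    n_per_group: int = 10,
    n_affected: int = 0,
    effect_log2fc: float = 1.0,
    noise_sd: float = 0.25,
    batch_sd: float = 0.2,
    sex_sd: float = 0.1,
    detection_rate: float = 1.0,
) -> OmicsTruth:
    """Draw per-feature effects for a two-group experiment.

    The first ``n_affected`` features carry a condition effect of
    ``effect_log2fc`` (alternating sign); all features receive random
    batch and sex offsets of the stated spreads.
    """
    rng = np.random.default_rng(seed)
    true = np.zeros(n_features)
    signs = np.where(np.arange(n_affected) % 2 == 0, 1.0, -1.0)
    true[:n_affected] = effect_log2fc * signs
    return OmicsTruth(
        true_log2fc=true,
        batch_effects=rng.normal(0.0, batch_sd, n_features),
        sex_effects=rng.normal(0.0, sex_sd, n_features),
        detection_rate=np.full(n_features, detection_rate),
        n_per_group=n_per_group,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_analyte_dataset(
    truth: OmicsTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate log2 abundances, sample metadata, and the peak-area form.

    Returns ``(values, metadata, extras)`` where ``values`` is the
    feature x sample log2 abundance matrix (with missingness applied),
    ``metadata`` has genotype, sex, batch, subject_id and methoxy_status
    columns, and ``extras`` carries the raw ``peak_areas``,
    ``standard_areas`` and ``standard_map`` (one internal standard per
    feature class) plus the ``truth_table`` of per-feature planted
    effects. ``normalize_internal_standard`` applied to the peak-area form
    reproduces ``values`` exactly (up to shared missingness).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_features
    n_samp = 2 * truth.n_per_group
    features = [f"feat_{i:04d}" for i in range(n)]
    samples = [f"s{j:02d}" for j in range(n_samp)]

    genotype = np.array(["WT"] * truth.n_per_group + ["KI"] * truth.n_per_group)
    sex = np.array(["F" if j % 2 == 0 else "M" for j in range(n_samp)])
    batch = np.array([f"day{(j // 2) % 2 + 1}" for j in range(n_samp)])
    metadata = pd.DataFrame(
        {
            "genotype": genotype,
            "sex": sex,
            "batch": batch,
            "subject_id": [f"m{j:02d}" for j in range(n_samp)],
            "methoxy_status": ["NA"] * n_samp,
        },
        index=samples,
    )

    cond = (genotype == "KI").astype(float)
    sex_ind = (sex == "M").astype(float)
    batch_ind = (batch == "day2").astype(float)

    values = (
        truth.baseline
        + np.outer(truth.true_log2fc, cond)
        + np.outer(truth.batch_effects, batch_ind)
        + np.outer(truth.sex_effects, sex_ind)
    )
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    values = pd.DataFrame(values, index=features, columns=samples)

    detected = rng.random(values.shape) < truth.detection_rate[:, None]
    values = values.where(detected)

    standard_map = {f: "IS_1" for f in features}
    standard_areas = pd.DataFrame(
        STANDARD_AREA, index=["IS_1"], columns=samples, dtype=float
    )
    peak_areas = STANDARD_AREA * np.exp2(values)

    truth_table = pd.DataFrame(
        {
            "true_log2fc": truth.true_log2fc,
            "batch_effect": truth.batch_effects,
            "sex_effect": truth.sex_effects,
            "detection_rate": truth.detection_rate,
        },
        index=features,
    )
    extras = {
        "peak_areas": peak_areas,
        "standard_areas": standard_areas,
        "standard_map": standard_map,
        "truth_table": truth_table,
    }
    return values, metadata, extras
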