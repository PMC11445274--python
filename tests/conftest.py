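"""Shared fixtures: small fast phantom cases for unit tests and one
study-scale cohort analysis (computed once per session) for the
acceptance-level checks."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from svxresp.features import extract_feature_table
from svxresp.geometry import ImageGeometry
from svxresp.labeling import label_voxels, znormalize_to_reference
from svxresp.modeling import RfConfig, cross_validate, grouped_folds
from svxresp.supervoxels import SlicConfig, majority_label, slic_supervoxels
from svxresp.synthetic import CohortConfig, default_cohort_config, generate_cohort


def small_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """A fast phantom configuration: 32 voxel grid, ~1000-voxel CET."""
    defaults = dict(
        n_patients=2,
        geometry=ImageGeometry((32, 32, 32)),
        tumor_radius_mm=6.5,
        rim_thickness_mm=3.0,
        edema_margin_mm=3.0,
        followup_growth_mm=1.0,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_case():
    """One small phantom case."""
    return generate_cohort(small_cohort_config(seed=3, n_patients=1))[0]


def analyze_case(bundle, threshold=0.10, slic_config=None):
    """Run labeling and clustering for one bundle; returns (labels, svx,
    majority table)."""
    from svxresp.features import prepare_channels

    channels = prepare_channels(bundle)
    svx = slic_supervoxels(
        channels, bundle.cet_mask, slic_config or SlicConfig(),
        spacing=bundle.geometry.spacing,
    )
    ref = bundle.nonenhancing_brain_mask()
    labels = label_voxels(
        znormalize_to_reference(bundle.channels["T1c"], ref),
        znormalize_to_reference(bundle.followup_T1c, ref),
        bundle.cet_mask,
        threshold,
    )
    return labels, svx, majority_label(svx, labels)


@dataclass
class CohortAnalysis:
    cases: list
    label_agreement: list[float]
    svx_maps: dict
    svx_labels: dict
    table: pd.DataFrame
    cv: object


@pytest.fixture(scope="session")
def study_cohort_analysis() -> CohortAnalysis:
    """The scaled study analogue: default 30-patient cohort with planted
    effects, run end to end in memory (labels from follow-up, SLIC,
    features, patient-grouped tenfold CV)."""
    cases = generate_cohort(default_cohort_config(seed=0))
    svx_maps, svx_labels, agreement = {}, {}, []
    for bundle in cases:
        labels, svx, table = analyze_case(bundle)
        truth = bundle.truth_labels
        cet = bundle.cet_mask
        agreement.append(float((labels.labels[cet] == truth.labels[cet]).mean()))
        svx_maps[bundle.case_id] = svx
        svx_labels[bundle.case_id] = table
    table = extract_feature_table(cases, svx_maps, svx_labels)
    cv = cross_validate(table, grouped_folds(table, 10, seed=0), RfConfig(seed=0))
    return CohortAnalysis(
        cases=cases,
        label_agreement=agreement,
        svx_maps=svx_maps,
        svx_labels=svx_labels,
        table=table,
        cv=cv,
    )
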