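"""Shared fixtures.

Expensive end-to-end artefacts (full default-phantom pipeline run,
zero-load run, wedge family) are session-scoped so the acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinedeform.deformation import jacobian_map
from spinedeform.disc_analysis import analyze_discs, dice_jaccard, propagate_mask
from spinedeform.phantom import PhantomSpec, generate_phantom
from spinedeform.registration import (
    RegistrationParams,
    register_bspline,
    register_rigid,
    transform_to_field,
)


def small_spec(**overrides) -> PhantomSpec:
    """Compact two-disc phantom for cheap registration tests."""
    base = dict(
        grid_shape=(48, 32, 80),
        spacing=(2.0, 2.0, 2.0),
        levels=("L4/L5", "L5/S1"),
        disc_centers_z=(96.0, 60.0),
        compression_factors=(0.93, 0.90),
        wedge_angles_deg=(1.0, 2.0),
        lateral_gradients=(0.0, 0.0),
        pfirrmann=(2, 3),
        seed=7,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    unloaded, loaded, truth, metadata = generate_phantom(spec)
    return spec, unloaded, loaded, truth, metadata


@pytest.fixture(scope="session")
def small_phantom_clean():
    """Noise-free variant of the small phantom."""
    spec = small_spec(noise_sigma=0.0)
    unloaded, loaded, truth, metadata = generate_phantom(spec)
    return spec, unloaded, loaded, truth, metadata


def two_stage(unloaded, loaded, params: RegistrationParams | None = None):
    params = params or RegistrationParams()
    rigid = register_rigid(unloaded, loaded, params)
    transform = register_bspline(unloaded, loaded, rigid, params)
    return transform


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline artefacts on the standard validation phantom.

    The registration QC, parameter-recovery and positivity checks all
    read from this single run.
    """
    spec = PhantomSpec()
    unloaded, loaded, truth, metadata = generate_phantom(spec)
    transform = two_stage(unloaded, loaded)
    field = transform_to_field(transform, unloaded)
    jmap = jacobian_map(field, unloaded.spacing)
    records = analyze_discs(
        jmap, truth.masks_unloaded, landmarks=truth.landmarks_loaded,
        metadata=metadata,
    )
    propagated = propagate_mask(truth.masks_loaded, transform, unloaded)
    overlap = dice_jaccard(propagated.data, truth.masks_unloaded.data)
    return {
        "spec": spec,
        "unloaded": unloaded,
        "loaded": loaded,
        "truth": truth,
        "metadata": metadata,
        "transform": transform,
        "field": field,
        "jmap": jmap,
        "records": records,
        "overlap": overlap,
    }


@pytest.fixture(scope="session")
def zero_load_run():
    """Pipeline artefacts for an unloaded-vs-unloaded (null) acquisition.

    All compression factors are 1 and wedge/lateral gradients are 0, but
    acquisition noise stays on, so any recovered deformation is spurious.
    """
    spec = PhantomSpec(
        compression_factors=(1.0,) * 5,
        wedge_angles_deg=(0.0,) * 5,
    )
    unloaded, loaded, truth, metadata = generate_phantom(spec)
    transform = two_stage(unloaded, loaded)
    field = transform_to_field(transform, unloaded)
    jmap = jacobian_map(field, unloaded.spacing)
    return {"spec": spec, "truth": truth, "jmap": jmap}


@pytest.fixture(scope="session")
def wedge_phantom_run():
    """Pure-wedge phantom at the standard resolution.

    Compression factors are all 1 so the anterior-posterior wedge
    (default grading -2 .. +2 degrees across the five discs) is the only
    deformation; the per-disc regional profiles isolate the wedge's
    regional signature, including its sign flip between cranial and
    caudal discs.
    """
    spec = PhantomSpec(compression_factors=(1.0,) * 5)
    unloaded, loaded, truth, metadata = generate_phantom(spec)
    transform = two_stage(unloaded, loaded)
    field = transform_to_field(transform, unloaded)
    jmap = jacobian_map(field, unloaded.spacing)
    records = analyze_discs(jmap, truth.masks_unloaded, metadata=metadata)
    return {"spec": spec, "truth": truth, "records": records}


def wedge_family_specs(n: int = 10) -> list[PhantomSpec]:
    """Graded-wedge family at reduced resolution.

    Member ``i`` applies one wedge angle (0.2 .. 2.0 degrees) uniformly
    to all five discs over a moderate uniform compression, so the
    anterior-posterior deformation gradient is the dominant regional
    signal; noise and texture match the standard phantom.
    """
    thetas = np.linspace(0.2, 2.0, n)
    return [
        PhantomSpec(
            grid_shape=(72, 48, 120),
            spacing=(2.0, 2.0, 2.0),
            compression_factors=(0.97,) * 5,
            wedge_angles_deg=(float(t),) * 5,
            seed=100 + i,
        )
        for i, t in enumerate(thetas)
    ]


@pytest.fixture(scope="session")
def wedge_family_run():
    """Registered per-disc records for every wedge-family member."""
    results = []
    for spec in wedge_family_specs():
        unloaded, loaded, truth, metadata = generate_phantom(spec)
        transform = two_stage(unloaded, loaded)
        field = transform_to_field(transform, unloaded)
        jmap = jacobian_map(field, unloaded.spacing)
        records = analyze_discs(
            jmap, truth.masks_unloaded, landmarks=truth.landmarks_loaded,
        )
        angles_unl = []
        from spinedeform.disc_analysis import _landmark_segment, disc_angle

        for lab in records["disc_id"]:
            lower = _landmark_segment(
                truth.landmarks_unloaded, int(lab), "superior_endplate_lower"
            )
            upper = _landmark_segment(
                truth.landmarks_unloaded, int(lab), "inferior_endplate_upper"
            )
            angles_unl.append(disc_angle(lower, upper))
        records["disc_angle_deg_unloaded"] = angles_unl
        records["disc_angle_change"] = (
            records["disc_angle_deg"] - records["disc_angle_deg_unloaded"]
        )
        results.append({"spec": spec, "records": records})
    return results
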