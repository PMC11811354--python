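import datetime as dt

import numpy as np
import pytest

from steatoscreen.dicom_io import InstanceMeta, SeriesStack
from steatoscreen.orchestrator import Orchestrator, OrchestratorConfig
from steatoscreen.phantom import AXIAL, PhantomConfig, generate_phantom, generate_volume

EPOCH = dt.datetime(2024, 1, 1, tzinfo=dt.timezone.utc)


def make_meta(
    *,
    study_uid="1.2.3.1",
    series_uid="1.2.3.1.1",
    sop_uid="1.2.3.1.1.1",
    instance_number=1,
    position=(0.0, 0.0, 0.0),
    orientation=AXIAL,
    pixel_spacing=(1.0, 1.0),
    thickness=3.0,
    slope=1.0,
    intercept=-1024.0,
    rows=4,
    cols=4,
    procedure_code="74176",
    contrast_agent=None,
    received_at=EPOCH,
):
    return InstanceMeta(
        study_uid=study_uid,
        series_uid=series_uid,
        sop_uid=sop_uid,
        instance_number=instance_number,
        image_position=tuple(position),
        image_orientation=tuple(orientation),
        pixel_spacing=tuple(pixel_spacing),
        slice_thickness=thickness,
        rescale_slope=slope,
        rescale_intercept=intercept,
        rows=rows,
        cols=cols,
        modality="CT",
        procedure_code=procedure_code,
        contrast_agent=contrast_agent,
        received_at=received_at,
    )


def stack_from_config(config: PhantomConfig):
    """In-memory SeriesStack for a phantom config (no DICOM round trip)."""
    vol, truth = generate_volume(config)
    thicknesses = config.thicknesses()
    orientation = tuple(config.orientation)
    normal = np.cross(orientation[:3], orientation[3:])
    metas = []
    for i in range(config.grid[0]):
        metas.append(
            make_meta(
                study_uid="1.9.9",
                series_uid="1.9.9.1",
                sop_uid=f"1.9.9.1.{i + 1}",
                instance_number=i + 1,
                position=tuple(normal * (i * config.spacing[0])),
                orientation=orientation,
                pixel_spacing=config.spacing[1:],
                thickness=thicknesses[i],
                rows=config.grid[1],
                cols=config.grid[2],
                procedure_code=config.procedure_code,
                contrast_agent=config.contrast_agent,
            )
        )
    stack = SeriesStack(
        meta=metas,
        voxels=vol,
        spacing=config.spacing,
        slice_thickness_set=frozenset(thicknesses),
    )
    return stack, truth


@pytest.fixture(scope="session")
def steatotic_study(tmp_path_factory):
    """Zero-noise steatotic phantom written as a DICOM study on disk."""
    out = tmp_path_factory.mktemp("steatotic")
    study_dir, truth = generate_phantom(PhantomConfig(seed=11), out)
    return study_dir, truth


@pytest.fixture
def orchestrator_env(tmp_path):
    """Fresh orchestrator over empty inbox/outboxes with a controllable clock."""

    class Env:
        def __init__(self):
            self.inbox = tmp_path / "inbox"
            self.pacs = tmp_path / "pacs"
            self.report = tmp_path / "report"
            self.work = tmp_path / "work"
            self.inbox.mkdir()
            self.now = EPOCH

        def clock(self):
            return self.now

        def config(self, **overrides):
            kwargs = dict(
                inbox=self.inbox,
                pacs_outbox=self.pacs,
                report_outbox=self.report,
                work_dir=self.work,
                retry_backoff=(0.0,),
            )
            kwargs.update(overrides)
            return OrchestratorConfig(**kwargs)

        def orchestrator(self, transport=None, **overrides):
            return Orchestrator(
                self.config(**overrides),
                clock=self.clock,
                transport=transport,
                sleeper=lambda s: None,
            )

    return Env()
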