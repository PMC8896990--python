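import numpy as np

from connpattern.timeseries import ROITimeSeriesSet


def make_timeseries(
    data,
    subject_id="S01",
    group="control",
    lesion_side="none",
    week="W1",
    tr=2.0,
    voxel_data=None,
):
    return ROITimeSeriesSet(
        subject_id=subject_id,
        group=group,
        lesion_side=lesion_side,
        week=week,
        tr_seconds=tr,
        data=data,
        voxel_data=voxel_data,
    )


def white_noise_timeseries(rng, n_volumes=200, **kwargs):
    return make_timeseries(rng.standard_normal((n_volumes, 10)), **kwargs)
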