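import numpy as np
import pandas as pd
import pytest

import octametrics as om


@pytest.fixture(scope="session")
def scp_truth():
    """A seeded noise-free SCP phantom shared across tests."""
    return om.generate_plexus_phantom(om.PhantomSpec.scp(seed=3))


@pytest.fixture(scope="session")
def dcp_truth():
    return om.generate_plexus_phantom(om.PhantomSpec.dcp(seed=4))


@pytest.fixture(scope="session")
def cc_truth():
    return om.generate_cc_phantom(om.PhantomSpec.cc(seed=5))


def quantify_cohort(eyes):
    """Long-format metrics frame for a simulated cohort (library-level)."""
    rows = []
    for eye in eyes:
        for (plexus, mode), img in eye.images.items():
            row = {"eye_id": eye.eye_id, "plexus": plexus.value,
                   "mode": mode.value, "pd_percent": np.nan,
                   "vld_percent": np.nan, "vdi_pixels": np.nan,
                   "fd_percent": np.nan}
            if plexus is om.Plexus.CC:
                row["fd_percent"] = om.compute_cc_metrics(img).total_fd_percent
            else:
                m = om.compute_vascular_metrics(img)
                row.update(pd_percent=m.pd_percent, vld_percent=m.vld_percent,
                           vdi_pixels=m.vdi_pixels)
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_28_metrics():
    """Quantified 28-eye synthetic cohort under default V1/V4 noise."""
    eyes = om.generate_cohort(28, seed=20201201)
    return quantify_cohort(eyes)
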