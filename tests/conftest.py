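import numpy as np
import pytest

from periodx.chart_model import (
    PatientProfile,
    PeriodontalChart,
    SiteMeasurement,
    ToothRecord,
)
from periodx.config import default_config
from periodx.decision_tree import default_tree

SITE_ORDER = ("MB", "B", "DB", "ML", "L", "DL")


def healthy_tooth(n, pd=3, bop=()):
    """A tooth with zero CAL: the margin sits pd mm coronal to the CEJ."""
    return ToothRecord(
        tooth_number=n,
        sites=tuple(
            SiteMeasurement(site_id=s, probing_depth_mm=pd, recession_mm=-pd,
                            bleeding_on_probing=s in bop)
            for s in SITE_ORDER
        ),
        bone_loss_percent=0.0,
    )


def make_chart(overrides=None, profile=None, chart_id="fixture", missing=()):
    """Full 32-tooth chart, healthy by default; overrides maps tooth -> ToothRecord."""
    overrides = overrides or {}
    teeth = {}
    for n in range(1, 33):
        if n in overrides:
            teeth[n] = overrides[n]
        elif n in missing:
            teeth[n] = ToothRecord(tooth_number=n, present=False)
        else:
            teeth[n] = healthy_tooth(n)
    return PeriodontalChart(
        chart_id=chart_id,
        profile=profile or PatientProfile(age_years=50),
        teeth=teeth,
    )


def diseased_tooth(n, cal, pd, bone_loss=30.0, site="MB", **tooth_kwargs):
    """Tooth with the given interdental CAL at one site, otherwise healthy."""
    sites = []
    for s in SITE_ORDER:
        if s == site:
            sites.append(SiteMeasurement(site_id=s, probing_depth_mm=pd, recession_mm=cal - pd))
        else:
            sites.append(SiteMeasurement(site_id=s, probing_depth_mm=3, recession_mm=-3))
    return ToothRecord(tooth_number=n, sites=tuple(sites), bone_loss_percent=bone_loss,
                       **tooth_kwargs)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)
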