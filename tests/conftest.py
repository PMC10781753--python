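import numpy as np
import pytest

from coastsqueeze import ShorePart, Shoreline, Transect, WorldSpec, generate_world


def make_transect(origin, azimuth, length_m=25_000.0, tid=0, frame="planar_m",
                  lat_ref=0.0, latitude_deg=float("nan")):
    az = np.asarray(azimuth, dtype=float)
    az = az / np.hypot(*az)
    return Transect(
        id=tid,
        origin=np.asarray(origin, dtype=float),
        azimuth=az,
        length_m=length_m,
        station_arc_m=0.0,
        frame=frame,
        lat_ref=lat_ref,
        latitude_deg=latitude_deg,
    )


def straight_shoreline(length_m=10_000.0, sandy=True, land_side="left"):
    return Shoreline(
        [ShorePart(np.array([[0.0, 0.0], [length_m, 0.0]]), np.array(sandy), land_side)]
    )


@pytest.fixture(scope="session")
def small_world():
    """50-km straight world with all label layers active."""
    return generate_world(WorldSpec(seed=3, shore_length_km=50.0))


@pytest.fixture(scope="session")
def acceptance_world():
    """~1,100-transect straight world at the default study conditions."""
    return generate_world(WorldSpec(seed=123, shore_length_km=1100.0))
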