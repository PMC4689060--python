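import logging
import warnings

import numpy as np
import pytest

import moveability as mv

logging.getLogger("moveability").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def window2km():
    return mv.Window.rectangle(2000.0, 2000.0)


@pytest.fixture(scope="session")
def uniform_pattern(window2km):
    rng = np.random.default_rng(101)
    pts = rng.uniform(0, 2000, size=(60, 2))
    return mv.PointPattern("transit", pts, window2km)


@pytest.fixture(scope="session")
def city_cfg():
    # a compact 2 km² town, point rates high enough for the CV selectors
    return mv.CityConfig(
        window_width_m=1600.0, window_height_m=1250.0, grid_spacing_m=100.0,
        edge_dropout_frac=0.1, density_peak_residents_km2=3500.0,
        density_floor_residents_km2=300.0, anisotropy_ratio=2.0,
        points_per_1000_residents={"transit": 12.0, "open_space": 10.0},
        raster_cell_m=50.0, seed=42)


@pytest.fixture(scope="session")
def city(city_cfg):
    network = mv.generate_street_network(city_cfg)
    density = mv.generate_density_raster(city_cfg)
    layers = {k: mv.generate_point_layer(k, density, network, city_cfg)
              for k in ("intersections", "transit", "open_space")}
    return {"config": city_cfg, "network": network, "density": density,
            "layers": layers, "window": city_cfg.window}


@pytest.fixture(scope="session")
def exposure_cfg():
    return mv.ExposureConfig(cell_size_m=50.0, blur=None)


@pytest.fixture(scope="session")
def open_space_surfaces(city, exposure_cfg):
    bws, surfs = mv.layer_surfaces(city["layers"]["open_space"], exposure_cfg)
    return bws, surfs
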