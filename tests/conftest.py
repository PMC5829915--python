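"""Shared fixtures: small rendered movies and simulated ensembles."""

import numpy as np
import pytest

from nm2motility.filament_simulator import (
    FilamentComposition,
    SimulationConditions,
    simulate_ensemble,
)
from nm2motility.synthetic_imaging import (
    OpticsModel,
    layout_actin,
    place_trajectories,
    render_background_stack,
    render_movie,
)


@pytest.fixture(scope="session")
def small_optics() -> OpticsModel:
    return OpticsModel(frame_count=60, image_shape=(128, 128))


@pytest.fixture(scope="session")
def nm2b_ensemble_2000():
    """2000 pure NM2-B runs at 30 motors/half, aqueous defaults.

    Session-scoped: reused by occupancy, exponentiality and monotonicity
    checks.
    """
    comp = FilamentComposition(n_motor_molecules_B=15)
    cond = SimulationConditions()
    return simulate_ensemble(comp, cond, 2000, seed=101)


@pytest.fixture(scope="session")
def rendered_movie_pack(small_optics):
    """Ten moving NM2-B filaments rendered at default SNR, with truth."""
    comp = FilamentComposition(n_motor_molecules_B=15)
    cond = SimulationConditions(
        actin_length=10.0,
        max_time=small_optics.frame_count * small_optics.frame_interval)
    table, trajs = simulate_ensemble(comp, cond, 10, seed=202,
                                     return_trajectories=True)
    layout = layout_actin(10, 10.0, small_optics.image_shape, seed=203,
                          orientation="rows", min_start_separation_um=1.2)
    placements = place_trajectories(trajs, layout, [{"488": 30}] * 10)
    movie = render_movie(placements, layout, small_optics, seed=204,
                         render_actin=False)
    background = render_background_stack(small_optics, 20, seed=205,
                                         channels=("488",))
    return {"table": table, "trajectories": trajs, "layout": layout,
            "movie": movie, "background": background}
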