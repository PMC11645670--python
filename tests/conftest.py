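import pytest

from hydrashell.distributions import ParametricDist
from hydrashell.hbonds import collect_samples
from hydrashell.synthetic import SyntheticShellModel, gen_frames


@pytest.fixture(scope="session")
def recovery_data():
    """~1e5 shell and bulk samples from frames with known generating densities.

    Shared by the moment/per-bin recovery tests; generation dominates the
    cost, so it runs once per session.
    """
    model = SyntheticShellModel(
        n_protein_atoms=120,
        protein_radius=35.0,
        n_shell_waters=200,
        n_bulk_waters=200,
        box_edge=120.0,
        seed=0,
    )
    frames = gen_frames(model, 500)
    shell = collect_samples(frames, "SHELL_ALL")
    bulk = collect_samples(frames, "BULK")
    return {"model": model, "shell": shell, "bulk": bulk}


@pytest.fixture
def point_mass_model():
    """Shell geometry pinned at (2.70 A, cos theta = -1); distinct bulk."""
    return SyntheticShellModel(
        n_shell_waters=20,
        n_bulk_waters=20,
        shell_d_dist=ParametricDist("point", loc=2.70, support=(2.3, 3.5)),
        shell_cos_dist=ParametricDist("point", loc=-1.0, support=(-1.0, 0.0)),
        bulk_d_dist=ParametricDist("truncnorm", loc=3.0, scale=0.1, support=(2.8, 3.5)),
        bulk_cos_dist=ParametricDist(
            "truncnorm", loc=-0.85, scale=0.05, support=(-1.0, -0.75)
        ),
        seed=7,
    )
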