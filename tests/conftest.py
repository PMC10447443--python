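import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """(topology, base coordinates) of the flexible toy molecule."""
    from shiftsel.synthetic import toy_template
    return toy_template()


@pytest.fixture(scope="session")
def small_trajectory():
    """A short packed trajectory with manifest, predictions, distributions."""
    from shiftsel.synthetic import generate_shifts, generate_trajectory
    snaps, manifest = generate_trajectory(n_snapshots=6, n_molecules=10,
                                          cell_side=24.0, seed=11)
    predictions, distributions = generate_shifts(snaps, manifest, seed=12)
    return snaps, manifest, predictions, distributions


@pytest.fixture(scope="session")
def small_environments(small_trajectory):
    from shiftsel.environments import extract_all_environments
    snaps, *_ = small_trajectory
    return extract_all_environments(snaps)


def brute_force_members(snapshot, central_index, cutoff, n_images=2):
    """Independent oracle: molecule membership by explicit enumeration of
    (2 n_images + 1)^3 periodic images, no minimum-image shortcuts."""
    import itertools
    lat = snapshot.cell.lattice
    pos = snapshot.positions
    shifts = np.array(list(itertools.product(range(-n_images, n_images + 1),
                                             repeat=3))) @ lat
    central = pos[central_index]
    members = {central_index}
    for other in range(pos.shape[0]):
        if other == central_index:
            continue
        best = np.inf
        for s in shifts:
            d = np.linalg.norm(central[:, None, :] - (pos[other] + s)[None, :, :],
                               axis=-1).min()
            best = min(best, d)
        if best <= cutoff:
            members.add(other)
    return members
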