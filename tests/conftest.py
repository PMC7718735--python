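"""Shared fixtures: small synthetic screens and nuclear fields.

Everything is generated at test time from seeded generators; no image files
ship with the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from mythscreen import calling, layout, synth


@pytest.fixture(scope="session")
def screen_config() -> synth.SynthScreenConfig:
    return synth.SynthScreenConfig(n_plates=3, seed=42)


@pytest.fixture(scope="session")
def library(screen_config) -> layout.LibraryLayout:
    return layout.default_layout(screen_config.n_plates)


@pytest.fixture(scope="session")
def bait_truth(screen_config, library) -> dict[str, str]:
    preys = [library.entries[a] for a in library.addresses()]
    return synth.draw_interactor_classes(preys, screen_config)


@pytest.fixture(scope="session")
def screen(screen_config, library, bait_truth) -> synth.ScreenData:
    """One simulated 3-plate screen (288 preys in quadruplicate)."""
    return synth.simulate_screen(screen_config, library, bait_truth)


@pytest.fixture(scope="session")
def labeled_colonies(screen_config):
    return synth.simulate_labeled_colonies(screen_config, n=120, seed=7)


@pytest.fixture(scope="session")
def screen_results(screen, library, labeled_colonies):
    """(interactome, spots, cutoff) of the fixture screen."""
    calls, spots, cutoff = calling.run_screen(
        screen.test_images,
        screen.diploid_images,
        library,
        labels=labeled_colonies,
        bait="bait1",
    )
    return calls, spots, cutoff


@pytest.fixture(scope="session")
def nucleus_field():
    """Stack with 20 in-range nuclei and 5 out-of-range/low-circularity objects."""
    specs = synth.make_nucleus_field(20, 5, seed=3)
    stack, truth = synth.render_nuclear_stack(specs, shape=(512, 512), noise_sd=0.0)
    return stack, truth
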