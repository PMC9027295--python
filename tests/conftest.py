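import numpy as np
import pytest

from mrmkit import chem, dataio, synth
from mrmkit.chem import Ms2Mode, parse_formula
from mrmkit.dataio import Chromatogram, MrmChannel, MrmTransition, Polarity, RunData
from mrmkit.synth import GaussianPeak, SimulationSpec, SyntheticCompound


def make_channel(q1, q3, polarity=Polarity.POSITIVE, ce=33.0, times=None, intensities=None):
    if times is None:
        times = np.linspace(0.0, 10.0, 101)
    if intensities is None:
        intensities = np.zeros_like(times)
    return MrmChannel(
        MrmTransition(q1=q1, q3=q3, polarity=polarity, ce=ce),
        Chromatogram(np.asarray(times, float), np.asarray(intensities, float)),
    )


@pytest.fixture
def pc_compounds():
    """PC 34:2 / 34:1 / 34:0 with the phosphocholine product ion."""
    product = parse_formula("C5H15O4NP")

    def pc(name, formula, q1, apex, height):
        return SyntheticCompound(
            name=name,
            formula=parse_formula(formula),
            ms2_formula=product,
            ms2_formula_type=Ms2Mode.CONSTANT_PRODUCT,
            transition=MrmTransition(q1, 184.07, Polarity.POSITIVE, 33.0),
            peaks=(GaussianPeak(apex, 0.08, height),),
        )

    return (
        pc("PC_34:2", "C42H81O8NP", 758.57, 4.0, 1000.0),
        pc("PC_34:1", "C42H83O8NP", 760.585, 4.6, 700.0),
        pc("PC_34:0", "C42H85O8NP", 762.6, 5.2, 500.0),
    )


@pytest.fixture
def simple_spec(pc_compounds):
    return SimulationSpec(
        compounds=pc_compounds,
        n_runs=2,
        sampling_interval=0.02,
        time_start=0.0,
        time_end=8.0,
        seed=11,
    )


def random_run(rng, n_channels=3, n_points=40, run_id="r"):
    """Random run with distinct transitions and nonnegative intensities."""
    channels = []
    q1s = np.sort(rng.uniform(300, 900, size=n_channels))
    while np.any(np.diff(q1s) < 0.5):
        q1s = np.sort(rng.uniform(300, 900, size=n_channels))
    for k in range(n_channels):
        times = np.linspace(0, 5, n_points)
        intensities = rng.uniform(0, 100, size=n_points)
        channels.append(
            make_channel(q1s[k], 184.0, times=times, intensities=intensities)
        )
    return RunData(run_id=run_id, channels=channels)
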