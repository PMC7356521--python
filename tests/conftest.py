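import pandas as pd
import pytest

import endosurf as es


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 500 proteins/line, CV 20%, seed 1."""
    return es.simulate_experiment(es.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    sim = default_sim
    return es.run_two_line_analysis(
        sim.quant_target, sim.quant_comparator, sim.annotations, sim.reference,
        fpkm=sim.fpkm, atlas=sim.atlas,
    )


@pytest.fixture(scope="session")
def noisefree_sim():
    return es.simulate_experiment(es.SimulationConfig(seed=1, noise_cv=0.0))


@pytest.fixture(scope="session")
def noisefree_pipeline(noisefree_sim):
    sim = noisefree_sim
    return es.run_two_line_analysis(
        sim.quant_target, sim.quant_comparator, sim.annotations, sim.reference,
        fpkm=sim.fpkm, atlas=sim.atlas,
    )


def quant_from_rows(rows, cell_line="line"):
    df = pd.DataFrame(rows, columns=["protein_id", "fraction", "replicate", "peak_area"])
    return es.QuantTable(cell_line=cell_line, data=df)


@pytest.fixture
def tiny_quant_tsv(tmp_path):
    """Minimal well-formed quant file: one protein, four fractions, 1 replicate."""
    path = tmp_path / "quant.tsv"
    lines = ["protein_id\tfraction\treplicate\tpeak_area"]
    for frac, area in [("Control", 100), ("Cell-surface", 800), ("Stripping", 80), ("Internalization", 160)]:
        lines.append(f"P1\t{frac}\t1\t{area}")
    path.write_text("\n".join(lines) + "\n")
    return path
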