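import sys
from pathlib import Path

import pyfaidx
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import latsplice as L


@pytest.fixture(scope="session")
def donor_model():
    """A PWM donor model over consensus-sampled 9-mers (fast to fit)."""
    return L.default_donor_model(seed=11, kind="pwm")


@pytest.fixture(scope="session")
def sim_bundle(donor_model, tmp_path_factory):
    """One simulated reference + experiment shared across read-only tests."""
    params = L.SimulationParams(seed=5)
    ref = L.generate_reference(params, donor_model)
    outdir = tmp_path_factory.mktemp("sim")
    ref.write(outdir)
    fasta = pyfaidx.Fasta(str(outdir / "ref.fa"))
    annotation = L.read_annotation([outdir / "genes.gtf"])
    catalog = L.build_catalog(annotation, fasta, donor_model, L.ScoreThreshold(0.0))
    experiment = L.simulate_experiment(ref, params)
    return {
        "params": params,
        "ref": ref,
        "outdir": outdir,
        "fasta": fasta,
        "annotation": annotation,
        "catalog": catalog,
        "experiment": experiment,
    }
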