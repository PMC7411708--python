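import textwrap
import warnings

import pytest

from sussol.schema import PROPERTY_NAMES
from sussol.synthetic import BlobSpec, make_blob_table
from sussol.table import read_solvent_table


def make_csv(tmp_path, rows, name="solvents.csv", header=None):
    """Write a small CSV fixture and return its path."""
    header = header if header is not None else ["Name", "CAS", *PROPERTY_NAMES]
    path = tmp_path / name
    lines = [",".join(header)] + [",".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def three_solvent_csv(tmp_path):
    """Three fully populated records covering the whole 22-property schema."""
    text = textwrap.dedent(
        """\
        Name,CAS,Boiling_point,Melting_point,Vapor_pressure,Flash_point,Autoignition_temperature,Hansen_delta_D,Hansen_delta_P,Hansen_delta_H,Solubility_in_water,Density,Viscosity,Relative_vapor_density,Log_P_octanol_water,Refractive_index,Surface_tension,Molar_volume,Relative_evaporation_rate,Antoine_A,Antoine_B,Antoine_C,Molecular_weight,Log_S
        Heptane,142-82-5,98.4,-90.6,46,-4,204,15.3,0,0,0.003,0.684,0.39,3.5,4.66,1.387,20.1,147,290,6.9,1268,216.9,100.2,-4.5
        1-Propanol,71-23-8,97.2,-126,21,23,371,16,6.8,17.4,1000,0.803,1.95,2.1,0.25,1.384,23.7,75,94,7.8,1500,205,60.1,1.0
        Butanone,78-93-3,79.6,-86.7,78,-9,404,16,9,5.1,275,0.805,0.4,2.5,0.29,1.379,24.6,90.1,380,7.1,1250,221,72.1,0.4
        """
    )
    path = tmp_path / "three.csv"
    path.write_text(text, encoding="utf-8")
    return path


@pytest.fixture
def three_solvent_table(three_solvent_csv):
    return read_solvent_table(three_solvent_csv)


@pytest.fixture(scope="session")
def blob_data():
    """Well-separated 3-family table with true labels (session-scoped)."""
    return make_blob_table(BlobSpec(k=3, n_per=10, seed=11))


@pytest.fixture(scope="session")
def blob_ensemble(blob_data):
    """SOM ensemble on the 3-family table: B = 10 x U runs on a 3x1 grid."""
    from sussol.som import run_ensemble
    from sussol.table import feature_matrix, select_feature_columns

    table, labels = blob_data
    features = feature_matrix(table, columns=select_feature_columns(table))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        assignments = run_ensemble(features, runs=30, base_seed=5, width=3, height=1)
    return table, labels, features, assignments
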