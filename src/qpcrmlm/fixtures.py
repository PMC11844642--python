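"""Packaged example data: the 10-sample GAPDH/MMP10 CT table and the two
simulation scenario grids.

The CT table is a published airway-epithelial-cell experiment: cells from
five cystic-fibrosis donors exposed to the CFTR-modulator combination ETI
(elexacaftor/tezacaftor/ivacaftor) or DMSO vehicle, with GAPDH as the
reference gene and MMP10 as the target.
"""

from __future__ import annotations

import io
from pathlib import Path

from .ct_data import CTTable, read_ct_table

TABLE2_CSV = """\
sample,subject,treatment,GAPDH,MMP10
KK22F DMSO,KK22F,DMSO,20.17,24.50
KK22F ETI,KK22F,ETI,20.55,25.96
KK32G DMSO,KK32G,DMSO,19.86,23.26
KK32G ETI,KK32G,ETI,19.66,23.92
KK27H DMSO,KK27H,DMSO,19.62,21.82
KK27H ETI,KK27H,ETI,19.72,22.44
KK29H DMSO,KK29H,DMSO,21.29,27.19
KK29H ETI,KK29H,ETI,21.01,28.37
KK18G DMSO,KK18G,DMSO,20.06,23.87
KK18G ETI,KK18G,ETI,20.49,24.82
"""

#: stable-reference grid: the reference gene does not respond to treatment
TABLE5_SCENARIO_YAML = """\
# Type I error / power grid with a stable reference gene
rhos: [0.0, 0.5, 0.9]
shapes: [gaussian, right_skewed, left_skewed]
n_per_group: 5
target_effect: 2.0
reference_effect: 0.0
alpha: 0.05
n_reps: 10000
seed: 20250213
"""

#: contaminated-reference grid: treatment shifts the reference by 1 SD
TABLE6_SCENARIO_YAML = """\
# Type I error / power grid with a treatment-responsive reference gene
rhos: [0.0, 0.5, 0.9]
shapes: [gaussian, right_skewed, left_skewed]
n_per_group: 5
target_effect: 2.0
reference_effect: 1.0
alpha: 0.05
n_reps: 10000
seed: 20250213
"""

_FILES = {
    "table2.csv": TABLE2_CSV,
    "table5.yaml": TABLE5_SCENARIO_YAML,
    "table6.yaml": TABLE6_SCENARIO_YAML,
}


def load_example_table() -> CTTable:
    """The packaged GAPDH/MMP10 CT table as a validated CTTable."""
    return read_ct_table(io.StringIO(TABLE2_CSV), layout="wide")


def write_fixtures(directory, force: bool = False) -> list[Path]:
    """Write the packaged example CSV and scenario files into ``directory``.

    Refuses to overwrite existing files unless ``force`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    existing = [name for name in _FILES if (directory / name).exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite existing file(s) {existing}; use force"
        )
    written = []
    for name, content in _FILES.items():
        path = directory / name
        path.write_text(content)
        written.append(path)
    return written
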