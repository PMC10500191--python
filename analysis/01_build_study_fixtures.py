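#!/usr/bin/env python
"""Write the study fixtures (marker map, proband genotypes, phenotype
cohort, literature totals) as plain-text inputs under data/.

Marker coordinates are reconstructed stand-ins chosen to reproduce the
published span sizes; see founderhap.fixtures for provenance notes.
"""

import json
from pathlib import Path

from founderhap.fixtures import (
    literature_cohort_counts,
    study_cohort,
    study_genotypes,
    study_map,
)
from founderhap.io import write_cohort, write_genotypes, write_map

DATA = Path(__file__).resolve().parent.parent / "data"


def main() -> None:
    DATA.mkdir(exist_ok=True)
    write_map(study_map(), DATA / "markers.map")
    write_genotypes(study_genotypes(), DATA / "genotypes.ped")
    write_cohort(study_cohort(), DATA / "cohort.tsv")
    (DATA / "literature_counts.json").write_text(
        json.dumps(literature_cohort_counts(), indent=2) + "\n"
    )
    print(f"wrote 11-marker map, 6 proband genotype rows, 27-carrier cohort "
          f"and literature totals to {DATA}")


if __name__ == "__main__":
    main()
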