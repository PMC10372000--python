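#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes the toy genome-scale network (biomass + ATP-maintenance objectives),
an FPKM-like expression matrix for 28 tumour and 3 control samples, the
glucose medium and the drug catalogue with planted selective / toxic / inert
drugs under results/study/, plus a ready-to-run pipeline config.
"""

from pathlib import Path

import yaml

from fluxscreen.pipeline import write_synthetic_inputs
from fluxscreen.synthetic import SyntheticSpec

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"


def main() -> None:
    spec = SyntheticSpec()
    config = write_synthetic_inputs(spec, STUDY)
    raw = {
        "model": config.model,
        "datasets": {k: {"expression": v.expression, "condition": v.condition}
                     for k, v in config.datasets.items()},
        "drugs": config.drugs,
        "medium": dict(config.medium),
        "outdir": config.outdir,
        "seed": config.seed,
    }
    (STUDY / "config.yaml").write_text(yaml.safe_dump(raw, sort_keys=False))
    print(f"cohort written under {STUDY}")
    print(f"  tumour samples : {spec.n_samples_cancer}")
    print(f"  control samples: {spec.n_samples_control}")
    print(f"  planted essential genes : {list(spec.planted_essential_genes)}")
    print(f"  planted selective drugs : {list(spec.planted_selective_drugs)}")
    print(f"  planted toxic drugs     : {list(spec.planted_toxic_drugs)}")
    print(f"config: {STUDY / 'config.yaml'}")


if __name__ == "__main__":
    main()
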