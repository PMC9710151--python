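"""Run the complete scaled-down experiment for one phenotype.

Simulation, harmonization, pre-selection, the three arms, and the final
accuracies, all driven by one config and one master seed.
"""

import json

from genotransfer.pipeline import run_phenotype, scaled_study_config

cfg = scaled_study_config(master_seed=1)
row = run_phenotype(cfg, 5, 1)

print(json.dumps(row, indent=1))
# no_transfer / snp_transfer / deep_transfer are final-hold-out (FD)
# accuracies in percent; "detail" records which sub-dataset, model and
# freeze plan each arm selected on the small population's test split.
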