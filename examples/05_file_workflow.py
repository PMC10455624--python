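"""The on-disk workflow: FASTA + species map in, report tables out.

Writes a simulated bundle to a temporary directory, reads it back
through the same input paths real data would take (aligned FASTA,
two-column species TSV), and builds the multi-dataset stress-test
report with its Count/AVE footer.  The same steps are available from
the shell via `barcode-gap simulate` and `barcode-gap stress`.
"""

import tempfile
from pathlib import Path

from barcodegap import pairwise_matrix, read_alignment, read_partition, split_pools
from barcodegap.gap import build_cutoff_table, build_report
from barcodegap.simulate import SimulationConfig, simulate_dataset, write_bundle

tmp = Path(tempfile.mkdtemp())
pools_by_dataset = {}
for name, seed in (("genus_a", 1), ("genus_b", 2)):
    bundle = write_bundle(
        simulate_dataset(SimulationConfig(seed=seed, dataset_name=name)), tmp
    )
    per_region = {}
    for region in ("nrITS", "ITS1", "ITS2"):
        aln = read_alignment(bundle[region], dataset_name=name, region=region)
        part = read_partition(bundle["species_map"], aln)
        per_region[region] = split_pools(
            pairwise_matrix(aln, "k80"), part, dataset_name=name, region=region
        )
    pools_by_dataset[name] = per_region

report = build_report(pools_by_dataset, [0.85, 0.90, 0.95])
print("stress-test report (footer row = gap count / mean size among gaps):")
print(report.to_string(index=False))
print()
cutoffs = build_cutoff_table(pools_by_dataset, level=0.95)
print("95% cutoff table (midpoints in percent divergence):")
print(cutoffs.to_string(index=False))
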