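"""Junction anatomy and poly(dA:dT) tract profiling.

Derives the core junction lengths from the packaged segment model of the
sequenced 4AL translocation junction, then synthesizes a junction-sized
sequence with a target homopolymer-tract frequency and re-measures it with
the scanner.
"""

from synbreak import (
    JunctionModel,
    JunctionSegment,
    SimulationConfig,
    core_junction_length,
    density_profile,
    scan_tracts,
    synthesize_junction_sequence,
)
from synbreak.fixtures import urartu_4al_junction

model = urartu_4al_junction()
print(f"stop-to-stop interval: {model.total_length} bp")
print(f"minus the two 3' UTRs: {core_junction_length(model, {'utr3'})} bp")
print(
    "minus the lineage-specific MITE (initial junction): "
    f"{core_junction_length(model, {'utr3'}, exclude_lineage_specific=True)} bp"
)

# synthesize a 2.5-kb junction with ~18.4 tracts/kb and re-measure
synthetic = JunctionModel("demo", [JunctionSegment("whole", "core", 2500)])
config = SimulationConfig(seed=7, tract_enrichment=18.4)
seq = synthesize_junction_sequence(synthetic, config)
profile = scan_tracts(seq, min_len=6)
dens = density_profile(profile, bin_size=100)
print(f"synthesized {len(seq)} bp; tracts >= 6 bp found: {len(profile.tracts)}")
print(f"measured frequency: {profile.frequency_per_kb():.1f}/kb (target 18.4/kb)")
print(f"densest 100-bp bin: {dens.max()} tract bases at offset {int(dens.argmax()) * 100}")
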