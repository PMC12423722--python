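"""Per-cycle feature extraction on a synthetic record.

Runs the full chain (clean, detect, screen, fiducials, decomposition) and
prints the named features of the first accepted cycle: timing intervals in
samples, second-derivative amplitude indices, and the height-derived
arterial path lengths.
"""

from wristpwv import pipeline, synth
from wristpwv.features import compute_body_lengths

rec = synth.synth_record(synth.RecordConfig(n_beats=10, pat_samples=150, seed=1))
vectors, exclusions = pipeline.extract_record(rec, height_cm=170.0)
print(f"accepted cycles: {len(vectors)}  excluded: {len(exclusions)}")

v = vectors[0]
named = ["p2o", "n_sys", "n_ms", "si", "pat", "pat2", "h2_over_pat2",
         "age_index", "age_index_v"]
for fid in named:
    if fid in v:
        print(f"  {fid:14s} = {v.get(fid):10.4f}   [{v.provenance[fid]}]")

lengths = compute_body_lengths(170.0, age=60.0, weight_kg=70.0)
print(f"  La (heart-ankle)    = {lengths.get('la'):.3f} cm")
print(f"  Lb (heart-brachium) = {lengths.get('lb'):.3f} cm")
print(f"  La - Lb             = {lengths.get('la_minus_lb'):.3f} cm")
# PAT echoes the planted 150 samples; P2O and SI are the timing features
# the regression models lean on
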