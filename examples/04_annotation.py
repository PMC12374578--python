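"""Annotate a merged segment-scan spectrum against the bundled compound table.

Peaks above the detection threshold are matched by [M-H]- adduct mass within
+-0.2 Da; identifications from both polarities combine by inclusion-exclusion.
"""

import segscan as ss

profile = ss.reference_profile()
sc = ss.SpaceChargeModel.calibrated(profile)
schedule = ss.plan_segments(50.0, 500.0, 20.0, 5.0)
merged = ss.merge_segments(
    ss.simulate_segment_run(
        profile, schedule, ss.AcquisitionSettings(injection_time=60.0), sc=sc
    ),
    schedule,
)

# detected peaks: interior local maxima above 5000 counts
inten = merged.intensity
is_max = (inten[1:-1] > inten[:-2]) & (inten[1:-1] > inten[2:]) \
    & (inten[1:-1] >= 5000.0)
peaks = [(float(m), "negative") for m in merged.mz[1:-1][is_max]]

table = ss.load_compound_table()
ids = ss.match(peaks, table, tolerance=0.2)
print(f"{len(peaks)} detected peaks, {len(ids)} candidate identifications, "
      f"{len({i.compound_id for i in ids})} distinct compounds\n")

print("best candidate per annotated peak:")
seen = set()
for ident in ids:
    if ident.peak_mz in seen:
        continue
    seen.add(ident.peak_mz)
    print(f"  m/z {ident.peak_mz:7.2f}  {ident.compound_name:30s} "
          f"{ident.adduct}  err {ident.mass_error:+.3f} Da")

# cross-polarity bookkeeping (counts of the survey scale)
pos = {f"c{i}" for i in range(177)}
neg = {f"c{i}" for i in range(56, 227)}
c = ss.cross_polarity_union(pos, neg)
print(f"\ncross-polarity union: {c.n_pos} positive + {c.n_neg} negative "
      f"with {c.n_both} shared -> {c.n_union} compounds")
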