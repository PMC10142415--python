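"""Categorize peaks by cluster presence and dichotomize bulk intensities.

Uses the synthetic Cnum fixture: per-cluster peak sets with known cluster
presence and bulk peaks whose log intensities rise with Cnum, the
constitutive (maximal-Cnum) group drawn from an explicit low/high mixture.
"""

import tempfile
from pathlib import Path

import nuhash as nh

clusters, bulk, truth = nh.simulate_cnum_fixture(n_peaks=2000, seed=3)
union = sorted({p for peaks in clusters.values() for p in peaks},
               key=lambda p: p.start)
print(f"{len(union)} union peaks across {len(clusters)} clusters, "
      f"{len(bulk)} bulk peaks")

records = nh.assign_cnum(union, clusters)
records, n_overlap = nh.attach_bulk(records, bulk)
print(f"{n_overlap} union peaks overlap a bulk peak")

records, threshold = nh.apply_intensity_groups(records)
print(f"constitutive-group intensity threshold: {threshold:.2f}")
print(nh.summarize_cnum(records).to_string())

# annotate against a tiny two-gene model to show the feature precedence
GTF = """\
chr1\ttoy\ttranscript\t100000\t200000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttoy\texon\t100000\t101000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttoy\tfive_prime_utr\t100000\t100200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttoy\ttranscript\t900000\t1000000\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr1\ttoy\texon\t999000\t1000000\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
"""
with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "toy.gtf"
    gtf.write_text(GTF)
    model = nh.GeneModel(gtf, promoter_window=2000)
    records = nh.annotate_features(records, model)

frame = nh.records_to_frame(records)
print("feature distribution:\n",
      frame.feature.value_counts(normalize=True).round(3).to_string())
tss = model.tss_positions()
dists = nh.distance_to_nearest([r.peak for r in records[:5]], tss)
print("distance to nearest TSS, first 5 peaks:", dists)
# Group sizes partition the union set; median bulk score rises with Cnum and
# the maximal group splits into the generating low/high components.
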