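"""Define a hash design and parse a single structured hash read.

Builds the bundled 4-sample reference design, writes/reloads it as YAML, and
walks one read through anchor location, cell-barcode correction, and sample
barcode matching.
"""

import tempfile
from pathlib import Path

import nuhash as nh
from nuhash.counting import WhitelistIndex

design = nh.reference_design()
print(f"{len(design.barcodes)} sample barcodes, "
      f"min pairwise Hamming distance {nh.min_pairwise_hamming(design)} "
      f"(tolerates {design.hash_mismatch_tol} mismatch unambiguously)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "design.yaml"
    nh.write_design(design, path)
    assert nh.load_design(path) == design
    print(f"design round-trips through YAML ({path.name})")

# a read laid out as anchor5 . UMI1 . sample barcode . UMI2 . anchor3,
# with one sequencing error inside the sample barcode
barcode = design.barcodes[1].sequence
damaged = "G" + barcode[1:] if barcode[0] != "G" else "T" + barcode[1:]
read = design.anchor5 + "AAAACCCC" + damaged + "GGGGTTTT" + design.anchor3

whitelist = WhitelistIndex(["ACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA"])
parsed = nh.parse_hash_read(read, "ACGTACGTACGTACGA", design, whitelist)
print(f"status={parsed.status.value} sample={parsed.sample_id} "
      f"cell={parsed.corrected_cell_barcode} umi={parsed.umi}")
# The read is valid: the damaged barcode is still uniquely nearest to
# NuHash-2 within tolerance, and the index read (one mismatch) was corrected
# to its unique whitelist neighbour.
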