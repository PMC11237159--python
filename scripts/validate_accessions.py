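#!/usr/bin/env python
"""Optional validation against the deposited glue-protein sequences.

These checks need sequence data that is not bundled with the package: fetch
the GenBank records OR483821 (PRIT-Dg), OR480786 (galectin-Dg1) and OR480788
(PRIT-Bm) as plain protein FASTA, then run

    python scripts/validate_accessions.py --prit-dg prit_dg.fa \
        --galectin-dg1 galectin_dg1.fa --prit-bm prit_bm.fa

Reported checks: galectin-Dg1 length (145 aa), PRIT-Dg glycine content
(13.7%), and the repeat unit lengths recovered by the tandem-repeat detector
(18 for PRIT-Dg, 8 for PRIT-Bm).
"""

import argparse

from glueevo.formats import read_fasta
from glueevo.properties import composition
from glueevo.repeats import detect_tandem_repeats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--prit-dg", help="protein FASTA of PRIT-Dg (OR483821)")
    parser.add_argument("--galectin-dg1", help="protein FASTA of galectin-Dg1 (OR480786)")
    parser.add_argument("--prit-bm", help="protein FASTA of PRIT-Bm (OR480788)")
    args = parser.parse_args()
    if args.galectin_dg1:
        (rec,) = read_fasta(args.galectin_dg1)
        print(f"galectin-Dg1 length: {len(rec)} aa (expected 145)")
    for name, path, expected_unit in (
        ("PRIT-Dg", args.prit_dg, 18),
        ("PRIT-Bm", args.prit_bm, 8),
    ):
        if not path:
            continue
        (rec,) = read_fasta(path)
        if name == "PRIT-Dg":
            gly = composition(rec).percent.get("G", 0.0)
            print(f"PRIT-Dg glycine content: {gly:.1f}% (expected 13.7%)")
        regions = detect_tandem_repeats(rec)
        units = sorted({r.unit_length for r in regions if r.copy_number >= 6})
        print(f"{name} repeat unit lengths (>= 6 copies): {units} (expected {expected_unit})")


if __name__ == "__main__":
    main()
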