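#!/usr/bin/env python
"""Stage 2 — genome selection: marine screen, quality filter, dedup.

Reads results/bundle/assembly_metadata.tsv, applies the marine keyword
screen, the N50/completeness/contamination/marker-gene thresholds and
per-strain deduplication, and writes the surviving assemblies to
results/qc_passed.tsv with a rejection log alongside.
"""

from pathlib import Path

import pandas as pd

from marinepde import qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = qc.read_assembly_metadata(ROOT / "bundle" /
                                        "assembly_metadata.tsv")
    marine, non_marine = qc.filter_marine(records)
    passed, rejections = qc.qc_filter(marine)
    final = qc.deduplicate_by_strain(passed)

    qc.write_assembly_metadata(final, ROOT / "qc_passed.tsv")
    log = pd.DataFrame(
        [{"assembly_id": r.assembly_id, "stage": "non-marine",
          "reasons": "isolation-source"} for r in non_marine]
        + [{"assembly_id": rej.record.assembly_id, "stage": "qc",
            "reasons": ",".join(rej.reasons)} for rej in rejections]
        + [{"assembly_id": r.assembly_id, "stage": "dedup",
            "reasons": "redundant-assembly"}
           for r in passed if r not in final]
    )
    log.to_csv(ROOT / "qc_rejections.tsv", sep="\t", index=False)

    print(f"{len(records)} assemblies: {len(non_marine)} non-marine, "
          f"{len(rejections)} failed QC, "
          f"{len(passed) - len(final)} redundant, {len(final)} retained")
    print(f"wrote {ROOT/'qc_passed.tsv'} and {ROOT/'qc_rejections.tsv'}")


if __name__ == "__main__":
    main()
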