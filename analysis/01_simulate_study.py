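#!/usr/bin/env python
"""Stage 1 — generate the synthetic study inputs.

Writes a ground-truthed bundle (reference set, proteomes, domain scans,
assembly metadata, taxonomy, tree, truth manifest) under results/bundle/.
Later stages consume only these files, mirroring a pipeline that starts
from downloaded data.
"""

from pathlib import Path

from marinepde import synthetic

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"


def main() -> None:
    bundle = synthetic.make_study_bundle(seed=SEED)
    bundle.write(OUT)
    manifest = bundle.manifest
    print(f"bundle written to {OUT}")
    print(f"  genomes: {manifest['n_genomes']} in "
          f"{len(manifest['genera'])} genera "
          f"{dict(manifest['genera'])}")
    print(f"  references: {manifest['reference']['n_references']} across "
          f"{len(manifest['reference']['counts']['cazy_family'])} families")
    print(f"  planted homologs: {len(manifest['planted'])}, "
          f"decoys: {len(manifest['decoys'])}")
    print(f"  constructed correlation structure: "
          f"{manifest['expected_edges']}")


if __name__ == "__main__":
    main()
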