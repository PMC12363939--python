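"""Fixture -> sanitize -> featurize -> evaluate run used by the
cross-process determinism check. Writes every artifact into the directory
given as argv[1], seeding all randomness from argv[2]."""

import json
import sys
from pathlib import Path

from structforge.conditioning import build_distance_template
from structforge.distill import extend_disordered_regions
from structforge.fixtures import (make_pathological_case, make_toy_peptide,
                                  perturb_structure)
from structforge.io import write_component_dictionary, write_mmcif
from structforge.metrics import lddt
from structforge.sanitize import sanitize_state


def main(out_dir: Path, seed: int) -> None:
    state, comps, _ = make_pathological_case("covalent_ligand", seed=seed)
    clean = sanitize_state(state, comps)
    write_mmcif(clean, out_dir / "sanitized.cif")
    write_component_dictionary(comps, out_dir / "components.cif")

    disordered, comps2 = make_toy_peptide("A" * 20, seed=seed,
                                          unresolved=range(15, 21))
    extended = extend_disordered_regions(disordered, seed=seed,
                                         components=comps2)
    write_mmcif(extended, out_dir / "extended.cif")

    ref, _ = make_toy_peptide("ACSA", seed=seed)
    pred = perturb_structure(ref, sigma=0.5, seed=seed)
    tpl = build_distance_template(ref, list(ref.table.uids))
    payload = {
        "lddt": lddt(pred, ref).global_score,
        "template_checksum": float(tpl.distances.sum()),
        "sanitize_atoms": len(clean.table),
    }
    (out_dir / "metrics.json").write_text(json.dumps(payload, sort_keys=True))


if __name__ == "__main__":
    main(Path(sys.argv[1]), int(sys.argv[2]))
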