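"""Regenerate the packaged data fixtures (toy ESST and signature-regressor
model) from fixed seeds.  Run from the repository root:

    python scripts/build_fixtures.py
"""

from pathlib import Path

from ddgscan.stability import (EnvironmentClass, calibrate_scale, derive_esst,
                               save_model, train_signature_model)
from ddgscan.synthetic import make_esst_family, make_families

DATA = Path(__file__).resolve().parent.parent / "src" / "ddgscan" / "data"

# substitutions expected to be strongly depleted in buried environments;
# used to calibrate the ESST scale so they score near -1 kcal/mol
CALIBRATION_SUBS = [
    ("L", "D", EnvironmentClass("helix", "buried")),
    ("I", "K", EnvironmentClass("helix", "buried")),
    ("V", "E", EnvironmentClass("strand", "buried")),
    ("F", "E", EnvironmentClass("strand", "buried")),
    ("M", "N", EnvironmentClass("coil", "buried")),
]


def main():
    spec, _ = make_esst_family(seed=11, n_homologs=200, columns_per_env=40)
    homologs = make_families(spec)
    esst = derive_esst([(spec.ancestral_sequence, homologs, spec.env_labels)],
                       pseudocount=1.0, scale=1.0)
    esst.scale = round(calibrate_scale(esst, CALIBRATION_SUBS, target=-1.0), 6)
    esst.write(DATA / "toy_esst.txt")
    print(f"toy ESST written (scale={esst.scale})")

    model, training = train_signature_model(seed=7)
    save_model(model, DATA / "signature_model.json")
    training.to_csv(DATA / "signature_training.csv", index=False)
    print(f"signature model written (n={model['n_training']}, "
          f"max residual={model['max_training_residual']:.3f})")


if __name__ == "__main__":
    main()
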