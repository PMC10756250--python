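"""Cross-validate the segmentation pipeline on a synthetic phantom cohort.

Renders 30 phantoms at 1 mm voxels and runs seeded 3-fold cross-validation
of the full method (affine atlas registration + fusion, 48-feature random
forest with background bias, map product).  Writes per-subject Dice scores
to results/crossval_dice.csv and prints the per-class mean +/- SD, which can
be compared against the floors expected of clean phantom data
(PS 0.97, anterior chamber 0.83, lens 0.82).

Runtime: roughly 15 minutes on one CPU.
"""

import sys
import time
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from oculomri.config import CohortConfig, SegmentationConfig  # noqa: E402
from oculomri.phantom import render_phantom, sample_phantom_spec  # noqa: E402
from oculomri.segmentation import LabelledSubject, cross_validate  # noqa: E402

SEED = 1
N_SUBJECTS = 30
K_FOLDS = 3


def main() -> None:
    t0 = time.time()
    cfg = CohortConfig()
    rng = np.random.default_rng(SEED)
    cohort = []
    for i in range(N_SUBJECTS):
        spec = sample_phantom_spec(cfg, rng, f"sub-{i:04d}")
        scan, labels = render_phantom(spec, intensity=cfg.intensity)
        cohort.append(LabelledSubject(spec.subject_id, scan, labels))
    print(f"rendered {N_SUBJECTS} phantoms in {time.time() - t0:.0f} s")

    report = cross_validate(cohort, K_FOLDS, SegmentationConfig(),
                            np.random.default_rng(SEED))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    report.per_subject.to_csv(results / "crossval_dice.csv", index=False)

    print(f"{K_FOLDS}-fold cross-validation ({time.time() - t0:.0f} s total)")
    summary = report.summary()
    for cls, row in summary.iterrows():
        print(f"  {cls:11s} Dice {row['mean']:.3f} +/- {row['sd']:.3f}")


if __name__ == "__main__":
    main()
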