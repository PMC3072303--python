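"""Regenerate the packaged synthetic locked-score coefficients.

Fits the ridge step of the classifier on the packaged synthetic reference
cohort (locked 23-gene structure as generative truth, recorded seed) and
writes src/cadscore/reference/locked_coefficients.txt.  The resulting
weights are demonstration placeholders — synthetic, non-clinical — used as
defaults by `cadscore.locked.default_coefficients()`.

Run from the repository root:  python scripts/make_reference_coefficients.py
"""

from pathlib import Path

from cadscore import locked, model

SEED = 17
N_SAMPLES = 640

OUT = Path(__file__).resolve().parents[1] / "src" / "cadscore" / "reference" \
    / "locked_coefficients.txt"


def fit_reference_coefficients(seed: int = SEED, n_samples: int = N_SAMPLES):
    structure = locked.locked_term_definitions()
    matrix, samples, _, _ = locked.locked_reference_cohort(n_samples=n_samples,
                                                           seed=seed)
    tv = locked.term_values(matrix, samples, structure).fillna(0.0)
    term_sex = {t: structure.term_sex(t) for t in structure.term_map}
    clf = model.CADClassifier(tv, samples, term_sex=term_sex)
    # no lasso step: the locked structure is fixed, only weights are fitted
    res = clf.fit(seed=seed, select=False)
    weights = {}
    for term in structure.term_map:
        main = res.fitted.coefficients.get(term, 0.0)
        inter = res.fitted.coefficients.get(f"{term}:male", 0.0)
        weights[term] = {"M": float(main + inter), "F": float(main)}
    return locked.LockedCoefficients(
        intercept=float(res.fitted.intercept),
        term_weights=weights,
        sex_coefficient=float(res.fitted.coefficients.get("sex_male", 0.0)),
        male_age_slope=float(res.fitted.coefficients.get("age_male", 0.0)),
        female_age_hinge_slope=float(
            res.fitted.coefficients.get("age_female_hinge", 0.0)),
        knot=60.0,
    )


def main():
    coeffs = fit_reference_coefficients()
    coeffs.save(OUT)
    text = OUT.read_text()
    OUT.write_text(
        "# SYNTHETIC reference coefficients — ridge fit on the packaged\n"
        f"# simulated cohort (n={N_SAMPLES}, seed={SEED}); non-clinical.\n"
        "# Regenerate with scripts/make_reference_coefficients.py\n" + text)
    print(f"wrote {OUT}")
    print(text)


if __name__ == "__main__":
    main()
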