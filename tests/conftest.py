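import pytest

from qtpower import calibrate_per_test_alpha

# Published power table of the original calculator for the HIV set-point
# study: heritability -> (power at N=486, power at N=2554).  Entries of
# 0.999 are capped/rounded values of powers >= 0.999.
TABLE2 = {
    0.010: (0.001, 0.442),
    0.014: (0.005, 0.787),
    0.020: (0.019, 0.977),
    0.030: (0.088, 0.999),
    0.040: (0.232, 0.999),
    0.050: (0.430, 0.999),
    0.060: (0.631, 0.999),
    0.070: (0.792, 0.999),
    0.080: (0.897, 0.999),
    0.090: (0.955, 0.999),
    0.100: (0.983, 0.999),
}

CALIBRATION_CELL = (0.07, 486, 0.792)  # H, N, published power


@pytest.fixture(scope="session")
def table2():
    return TABLE2


@pytest.fixture(scope="session")
def calibrated_alpha():
    """Per-test alpha implied by the published (H=7%, N=486) = 0.792 cell.

    The published table was produced with the normal approximation, so the
    calibration root-find uses that method; the recovered alpha is ~1.77e-7
    (about 283k SNPs under a Bonferroni family alpha of 0.05).
    """
    h, n, p = CALIBRATION_CELL
    return calibrate_per_test_alpha(h, n, p, method="normal")
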