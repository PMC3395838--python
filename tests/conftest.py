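import pytest

from phylofoot import log_odds_transform
from phylofoot.simulate import generate_random_pwm


@pytest.fixture
def random_loms():
    """Seeded log-odds matrices of mixed widths/information content."""
    def make(n=20, widths=range(3, 9), concentration=0.3, seed0=100):
        loms = []
        widths = list(widths)
        for i in range(n):
            w = widths[i % len(widths)]
            pwm = generate_random_pwm(w, concentration, seed=seed0 + i,
                                      pwm_id=f"R{i:03d}")
            loms.append(log_odds_transform(pwm))
        return loms
    return make
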