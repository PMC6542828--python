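from __future__ import annotations

from pathlib import Path

import pytest

from g2pfilter.engine import FilterConfig, filter_cohort, read_sex_table
from g2pfilter.panel import read_g2p_csv, reportable_entries, write_g2p_csv
from g2pfilter.synthetic import SimulationConfig, generate_cohort, generate_panel

FIVE_ROW_PANEL = """\
gene symbol,gene mim,disease name,confidence category,allelic requirement,mutation consequence,phenotypes,organ specificity list,pmids
BRCA2,600185,FANCONI ANEMIA,confirmed,biallelic,loss_of_function,HP:0001875;HP:0000252,Blood;Skeleton,11239453
SCN1A,182389,EPILEPTIC ENCEPHALOPATHY,confirmed,monoallelic,loss_of_function,HP:0001250,Brain,17347258
MECP2,300005,RETT SYNDROME,confirmed,x_linked_dominant,loss_of_function,HP:0002187,Brain,10508514
FGFR3,134934,ACHONDROPLASIA,probable,monoallelic,activating,HP:0011405,Skeleton,7913883
DUX4,606009,UNCERTAIN MYOPATHY,possible,monoallelic,uncertain,HP:0003198,Muscle,20724583
"""


@pytest.fixture()
def five_row_panel(tmp_path: Path):
    path = tmp_path / "five.csv"
    path.write_text(FIVE_ROW_PANEL)
    return read_g2p_csv(path)


@pytest.fixture(scope="session")
def sim(tmp_path_factory) -> dict:
    """A 50-sample synthetic cohort with background noise, filtered once."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=11, n_case_samples=25, n_control_samples=25,
                           background_rate=2.0)
    panel = generate_panel(cfg)
    panel_path = out / "panel.csv"
    write_g2p_csv(panel, panel_path)
    vcf, ped, truth = generate_cohort(cfg, panel, out)
    sex = read_sex_table(ped)
    fcfg = FilterConfig()
    result = filter_cohort(vcf, reportable_entries(panel), fcfg, sex)
    return {
        "cfg": cfg,
        "panel": panel,
        "panel_path": panel_path,
        "vcf": vcf,
        "ped": ped,
        "sex": sex,
        "truth": truth,
        "filter_cfg": fcfg,
        "result": result,
        "dir": out,
    }


@pytest.fixture(scope="session")
def noiseless(tmp_path_factory) -> dict:
    """Planted causatives only: every truth variant respects all thresholds."""
    out = tmp_path_factory.mktemp("noiseless")
    cfg = SimulationConfig(seed=7, n_case_samples=20, n_control_samples=10,
                           background_rate=0.0, offpanel_rate=0.0)
    panel = generate_panel(cfg)
    vcf, ped, truth = generate_cohort(cfg, panel, out)
    sex = read_sex_table(ped)
    result = filter_cohort(vcf, reportable_entries(panel), FilterConfig(), sex)
    return {"cfg": cfg, "panel": panel, "vcf": vcf, "ped": ped, "sex": sex,
            "truth": truth, "result": result, "dir": out}
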