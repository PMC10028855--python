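{
 "signatures": [
  "ASC_Smith.json",
  "Autophagy_ChenH.json",
  "Autophagy_ChenM.json",
  "Autophagy_Wang.json",
  "Autophagy_Xu.json",
  "CIN_Carter.json",
  "CIS_Robertson.json",
  "CellCycle_Davoli.json",
  "CellCycle_Lundberg.json",
  "Chemokines_Messina.json",
  "ConsensusOV_Chen.json",
  "DNArep_Kang.json",
  "ECM_Chakravarthy.json",
  "EMT_Cheng.json",
  "EMT_Mak.json",
  "EMT_Miow.json",
  "ExpandedImmune_Ayers.json",
  "Ferroptosis_Li.json",
  "Ferroptosis_Liang.json",
  "Ferroptosis_Liu.json",
  "Ferroptosis_Ye.json",
  "Glycolysis_Xu.json",
  "Glycolysis_Zhang.json",
  "HRDS_Lu.json",
  "Hypoxia_Buffa.json",
  "IFN_Ayers.json",
  "IPRES_Hugo.json",
  "IPSOV.json",
  "IPS_Charoentong.json",
  "ISC_MerlosSuarez.json",
  "ImmuneCyt_Davoli.json",
  "ImmuneCyt_Rooney.json",
  "ImmunoScore_Hao.json",
  "ImmunoScore_Roh.json",
  "LipidMetabolism_Zheng.json",
  "Matrisome_Yuzhalin.json",
  "MitoticIndex_Yang.json",
  "PassON_Du.json",
  "Pyroptosis_Li.json",
  "Pyroptosis_Lin.json",
  "Pyroptosis_Shao.json",
  "Pyroptosis_Ye.json",
  "StemCellCD49f_Smith.json",
  "TLS_Cabrita.json",
  "Tinflam_Ayers.json",
  "VEGF_Hu.json",
  "platinumResistanceSign.json"
 ]
}
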