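# Y-chromosome haplogroup marker definitions over five intron regions
# (DDX3Y intron 1, DDX3Y intron 7, UTY intron 19, ZFY intron 9, ZFY intron 10;
# 3,169 bp in total).
#
# The marker set is the published one: five SNPs, one (AT)n microsatellite and
# one 2-bp (GT) indel, with anchor coordinates as reported for the GenBank
# intron sequences (DDX3Y intron 1 SNP at 425 and microsatellite at 363 in
# AY928816; DDX3Y intron 7 SNP at 165 in AY928817; UTY intron 19 SNP cited
# both as position 423 in AY936543 and under AY936542 elsewhere - both ids are
# carried, no guess made; ZFY SNPs at 120 in AY928828 and 609 in AY928827;
# ZFY indel at 651 in AY936548).  Note the source table's footnote labels the
# ZFY markers "ZFY4/ZFY5" while its header says intron 9/10; the neutral ids
# zfy9/zfy10 follow the header.
#
# The REGION SEQUENCES this package simulates are SYNTHETIC stand-ins for the
# GenBank introns (not downloaded); they carry the Y2 allele states as the
# reference frame.  Allele rows Y1/Y2/Y3 below are the published states.
regions:
  ddx3y1:
    length: 700
    accession_note: "synthetic stand-in for AY928816 / AY928811"
  ddx3y7:
    length: 650
    accession_note: "synthetic stand-in for AY928817 / AY928819"
  uty19:
    length: 620
    accession_note: "synthetic stand-in for AY936543 (also cited AY936542)"
  zfy9:
    length: 500
    accession_note: "synthetic stand-in for AY928828 / AY928823"
  zfy10:
    length: 699
    accession_note: "synthetic stand-in for AY928827 / AY936548 / BOSZFY3"
markers:
  ddx3y1_snp:       {region: ddx3y1, type: snp,   position: 425}
  ddx3y1_at_repeat: {region: ddx3y1, type: microsatellite, position: 363, unit: AT}
  ddx3y7_snp:       {region: ddx3y7, type: snp,   position: 165}
  uty19_snp:        {region: uty19,  type: snp,   position: 423}
  zfy9_snp:         {region: zfy9,   type: snp,   position: 120}
  zfy10_snp:        {region: zfy10,  type: snp,   position: 609}
  zfy10_indel:      {region: zfy10,  type: indel, position: 651, motif: GT}
haplogroups:
  Y1: {taxon: "Bos taurus",  ddx3y1_snp: C, ddx3y1_at_repeat: 10, ddx3y7_snp: C, uty19_snp: C, zfy9_snp: C, zfy10_snp: C, zfy10_indel: absent}
  Y2: {taxon: "Bos taurus",  ddx3y1_snp: C, ddx3y1_at_repeat: 10, ddx3y7_snp: C, uty19_snp: A, zfy9_snp: C, zfy10_snp: C, zfy10_indel: present}
  Y3: {taxon: "Bos indicus", ddx3y1_snp: T, ddx3y1_at_repeat: 8,  ddx3y7_snp: T, uty19_snp: A, zfy9_snp: T, zfy10_snp: T, zfy10_indel: present}
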