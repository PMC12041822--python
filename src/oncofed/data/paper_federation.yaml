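name: paper_federation
entity_map: builtin
description: 'Six-site synthetic federation whose combined entity and gender totals
  equal the published worked-example figures (17,885 cases; 7969 W / 9913 M / 3
  D; site 5: 2045 cases, 500 melanoma). The split across sites 1-4 and 6 is arbitrary;
  site 4 lacks breast/uterus and site 5 has reduced gyn/urology counts, mirroring
  the documented site idiosyncrasies.'
sites:
- site_id: site1
  year: 2022
  mode: exact
  seed: 101
  cells:
    biliary:
      M: 20
      W: 18
    bladder:
      M: 93
      W: 34
    brain_cns:
      M: 41
      W: 34
    breast:
      M: 16
      W: 634
    cervix:
      W: 190
    colorectum:
      M: 177
      W: 92
    esophagus:
      M: 65
      W: 20
    hodgkin_lymphoma:
      M: 21
      W: 16
    kidney:
      M: 60
      W: 33
    larynx:
      M: 58
      W: 14
    leukemia:
      M: 69
      W: 48
    lip_oral_pharynx:
      M: 216
      W: 94
    liver:
      M: 55
      W: 24
    lung:
      M: 196
      W: 121
    melanoma:
      M: 212
      W: 172
    multiple_myeloma:
      M: 24
      W: 20
    non_hodgkin_lymphoma:
      M: 124
      W: 69
    ovary:
      W: 80
    pancreas:
      M: 80
      W: 76
    prostate:
      M: 652
    stomach:
      M: 53
      W: 36
    testis:
      M: 63
    thyroid:
      M: 51
      W: 118
    uterus:
      W: 137
- site_id: site2
  year: 2022
  mode: exact
  seed: 102
  cells:
    biliary:
      M: 18
      W: 16
    bladder:
      M: 83
      W: 30
    brain_cns:
      M: 36
      W: 30
    breast:
      W: 564
    cervix:
      W: 169
    colorectum:
      M: 157
      W: 82
    esophagus:
      M: 58
      W: 17
    hodgkin_lymphoma:
      M: 18
      W: 14
    kidney:
      M: 53
      W: 30
    larynx:
      M: 52
      W: 8
    leukemia:
      M: 61
      W: 43
    lip_oral_pharynx:
      M: 192
      W: 84
    liver:
      M: 49
      W: 22
    lung:
      D: 3
      M: 174
      W: 107
    melanoma:
      M: 188
      W: 153
    multiple_myeloma:
      M: 21
      W: 17
    non_hodgkin_lymphoma:
      M: 110
      W: 62
    ovary:
      W: 71
    pancreas:
      M: 71
      W: 67
    prostate:
      M: 580
    stomach:
      M: 47
      W: 32
    testis:
      M: 56
    thyroid:
      M: 45
      W: 105
    uterus:
      W: 121
- site_id: site3
  year: 2022
  mode: exact
  seed: 103
  cells:
    biliary:
      M: 15
      W: 14
    bladder:
      M: 72
      W: 26
    brain_cns:
      M: 32
      W: 26
    breast:
      W: 493
    cervix:
      W: 148
    colorectum:
      M: 138
      W: 72
    esophagus:
      M: 50
      W: 15
    hodgkin_lymphoma:
      M: 16
      W: 12
    kidney:
      M: 47
      W: 26
    larynx:
      M: 45
      W: 7
    leukemia:
      M: 54
      W: 38
    lip_oral_pharynx:
      M: 168
      W: 73
    liver:
      M: 43
      W: 19
    lung:
      M: 152
      W: 94
    melanoma:
      M: 165
      W: 133
    multiple_myeloma:
      M: 19
      W: 15
    non_hodgkin_lymphoma:
      M: 96
      W: 54
    ovary:
      W: 62
    pancreas:
      M: 62
      W: 59
    prostate:
      M: 507
    stomach:
      M: 41
      W: 28
    testis:
      M: 49
    thyroid:
      M: 39
      W: 92
    uterus:
      W: 106
- site_id: site4
  year: 2022
  mode: exact
  seed: 104
  cells:
    biliary:
      M: 12
      W: 12
    bladder:
      M: 59
      W: 21
    brain_cns:
      M: 26
      W: 21
    cervix:
      W: 120
    colorectum:
      M: 111
      W: 58
    esophagus:
      M: 41
      W: 12
    hodgkin_lymphoma:
      M: 13
      W: 10
    kidney:
      M: 38
      W: 21
    larynx:
      M: 36
      W: 6
    leukemia:
      M: 43
      W: 30
    lip_oral_pharynx:
      M: 136
      W: 59
    liver:
      M: 35
      W: 15
    lung:
      M: 123
      W: 76
    melanoma:
      M: 134
      W: 108
    multiple_myeloma:
      M: 15
      W: 12
    non_hodgkin_lymphoma:
      M: 78
      W: 44
    ovary:
      W: 50
    pancreas:
      M: 50
      W: 48
    prostate:
      M: 411
    stomach:
      M: 33
      W: 22
    testis:
      M: 39
    thyroid:
      M: 32
      W: 75
- site_id: site5
  year: 2022
  mode: exact
  seed: 105
  cells:
    biliary:
      M: 9
      W: 8
    bladder:
      M: 75
      W: 15
    brain_cns:
      M: 18
      W: 15
    breast:
      W: 40
    cervix:
      W: 15
    colorectum:
      M: 125
      W: 65
    esophagus:
      M: 50
      W: 8
    hodgkin_lymphoma:
      M: 9
      W: 7
    kidney:
      M: 48
      W: 26
    larynx:
      M: 25
      W: 5
    leukemia:
      M: 65
      W: 41
    lip_oral_pharynx:
      M: 140
      W: 40
    liver:
      M: 25
      W: 10
    lung:
      M: 155
      W: 85
    melanoma:
      M: 275
      W: 225
    multiple_myeloma:
      M: 11
      W: 8
    non_hodgkin_lymphoma:
      M: 55
      W: 30
    ovary:
      W: 5
    pancreas:
      M: 35
      W: 33
    prostate:
      M: 60
    stomach:
      M: 45
      W: 27
    testis:
      M: 28
    thyroid:
      M: 22
      W: 52
    uterus:
      W: 10
- site_id: site6
  year: 2021
  mode: exact
  seed: 106
  cells:
    biliary:
      M: 8
      W: 7
    bladder:
      M: 38
      W: 14
    brain_cns:
      M: 17
      W: 14
    breast:
      W: 259
    cervix:
      W: 77
    colorectum:
      M: 72
      W: 38
    esophagus:
      M: 26
      W: 8
    hodgkin_lymphoma:
      M: 8
      W: 6
    kidney:
      M: 24
      W: 14
    larynx:
      M: 24
    leukemia:
      M: 28
      W: 20
    lip_oral_pharynx:
      M: 88
      W: 39
    liver:
      M: 23
      W: 10
    lung:
      M: 80
      W: 49
    melanoma:
      M: 86
      W: 70
    multiple_myeloma:
      M: 10
      W: 8
    non_hodgkin_lymphoma:
      M: 51
      W: 28
    ovary:
      W: 32
    pancreas:
      M: 32
      W: 31
    prostate:
      M: 266
    stomach:
      M: 21
      W: 15
    testis:
      M: 25
    thyroid:
      M: 21
      W: 48
    uterus:
      W: 56
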