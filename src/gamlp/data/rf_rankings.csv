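target,rank,factor_id
Hinselmann,1,1
Hinselmann,2,9
Hinselmann,3,3
Hinselmann,4,2
Hinselmann,5,4
Hinselmann,6,31
Hinselmann,7,6
Hinselmann,8,7
Hinselmann,9,23
Hinselmann,10,11
Hinselmann,11,17
Hinselmann,12,12
Hinselmann,13,8
Hinselmann,14,29
Hinselmann,15,14
Hinselmann,16,5
Hinselmann,17,26
Hinselmann,18,16
Schiller,1,1
Schiller,2,9
Schiller,3,3
Schiller,4,4
Schiller,5,2
Schiller,6,11
Schiller,7,7
Schiller,8,8
Schiller,9,17
Schiller,10,6
Schiller,11,31
Schiller,12,12
Schiller,13,5
Schiller,14,23
Schiller,15,29
Schiller,16,16
Schiller,17,26
Schiller,18,10
Cytology,1,1
Cytology,2,3
Cytology,3,9
Cytology,4,2
Cytology,5,4
Cytology,6,7
Cytology,7,11
Cytology,8,6
Cytology,9,23
Cytology,10,31
Cytology,11,32
Cytology,12,26
Cytology,13,8
Cytology,14,5
Cytology,15,14
Cytology,16,18
Cytology,17,12
Cytology,18,29
Biopsy,1,1
Biopsy,2,9
Biopsy,3,3
Biopsy,4,4
Biopsy,5,2
Biopsy,6,12
Biopsy,7,7
Biopsy,8,11
Biopsy,9,32
Biopsy,10,8
Biopsy,11,6
Biopsy,12,17
Biopsy,13,18
Biopsy,14,10
Biopsy,15,5
Biopsy,16,29
Biopsy,17,30
Biopsy,18,21
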