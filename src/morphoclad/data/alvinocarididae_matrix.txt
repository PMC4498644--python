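# Morphological character matrix of Alvinocarididae (33 taxa x 63 characters).
# States 0-3; ? = missing, - = inapplicable, [ab] = polymorphic.
#
# Transcription provenance notes:
# * The published table typesets the two consecutive inapplicable scores for
#   characters 19-20 (dorsal-organ extent and lobation, blank when character
#   18 = 0) as a dash ligature; these are restored to two scores here.  The
#   restoration is structural for 14 rows; for Alvinocaridinides formosa
#   (printed with 18 = 1 yet a dash at 19) the same two-dash reading is the
#   judgement call adopted, being the least committal (inapplicable scores
#   enter the analysis as unknowns).
# * Row labels are kept as printed.  "Rimicaris_loihi" is the table's label
#   for the species the text retains as Opaepele loihi; "Alvinocaris_chelis"
#   is the table's spelling of A. chelys.  Both are flagged as aliases in
#   the loader, not renamed.
Acanthephyra_purpurea        1201012111222000100--00000-000001011011011011110101111011000000
Alpheus_echiurophilus        1001110001000000000--00000-001001101101111110000001000010000010
Alvinocaris_alexander        1100002130211121110--01000-1010000100100100[01]1110001111001000010
Alvinocaris_brevitelsonis    1200002220212111110--01000-101000010010010011110001111001000010
Alvinocaris_chelis           1100002230201121110--01000-101000010010010001110000111001000010
Alvinocaris_dissimilis       1200002230211121110--01000-1010000100100100111100011110?1000010
Alvinocaris_komaii           1200002120212121110--010111100000010010010011101001110110100010
Alvinocaris_longirostris     1200002120222121110--01000-101000010010010011110001111001000010
Alvinocaris_lusca            1100002120212111110--01010-101000010010010011110001111011000010
Alvinocaris_markensis        1100002230222121110--110110101000010010010011110001111011000010
Alvinocaris_methanophila     1100002230222121110--01000-101000010010010011110001111001000010
Alvinocaris_muricola         1200002130222121110--01000-101000010010010011110001111011000010
Alvinocaris_niwa             1100002110[02]11001110--1100[01]01010000100100100111100011110?1000010
Alvinocaris_williamsi        1100002120000121110--01010-1010000100100100111100011110?1000010
Alvinocaris_solitaire        1200002330211221110--110110101000010010010011110001111011000010
Alvinocaris_stactophila      1100002230211221110--01010-1010000100100100111100011110?1000010
Alvinocaridinides_formosa    1001112231000000111--00100-0100000100100000[01]000100[01]000100100010
Rimicaris_chacei             10111100010000000011000100-010000010010000000001000000100100001
Rimicaris_paulexa            10111100010000000111000100-010000010010000000001000000100100001
Rimicaris_vandoverae         10111100010000000111000100-010000010010000000001000000100100001
Rimicaris_parva              10111100010000001011000100-010000010010000000001000000100100001
Rimicaris_variabilis         10111100010000001111000100-010000010010000000001000000100100001
Rimicaris_susannae           10111100010000001011000100-01000001001000000000100[01]000100100001
Rimicaris_exoculata          0-111100010000000011100100-010110000000000000001000000100100001
Rimicaris_kairei             0-111100010000000011100100-010110000000000000001000000100100001
Rimicaris_hybisae            10111100010000000011200100-010010010010000000001000000100100001
Rimicaris_loihi              101111[01]0111010001110010100-010000010010000000001000000100100010
Shinkaicaris_leurokolos      11010021110001101110000100-010000010010000000001000000100100010
Manuscaris_acuminata         11010022210001101110011000-010000010010010010001000000100100010
Mirocaris_fortunata          10111100010000001110000110-10000111111111111001011[01]001001011110
Mirocaris_indica             10111100010000001110000110-10000111111111111001011[01]001001011110
Nautilocaris_saintlaurentae  11011120110010001110010110-100001111111111110010111001001011110
Keldyshicaris_vavilovi       10111111111010001110011010-101000010010010010010001001011000010
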