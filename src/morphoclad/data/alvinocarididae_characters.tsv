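# index	label	state labels (semicolon-separated); characters are unordered
0	Rostrum presence	absent;present
1	Rostrum length	not reaching end of 1st antennular segment;reaching end of 1st antennular segment;overreaching end of 2nd antennular segment
2	Rostrum tip	acute;obtuse
3	Rostrum lateral compression	laterally compressed;not laterally compressed
4	Rostrum dorsoventral compression	not dorsoventrally compressed;dorsoventrally compressed
5	Rostrum dorsal carina	dorsally carinate;not dorsally carinate
6	Rostrum dorsal armature	dorsally smooth;dorsally notched;dorsally toothed
7	Rostrum minimal dorsal teeth or notches	0;5-10;11-15;16 or more
8	Rostrum maximal dorsal teeth or notches	0;4-10;11-15;16 or more
9	Rostrum ventral carina	ventrally carinate;not ventrally carinate
10	Rostrum ventral armature	ventrally smooth;ventrally notched;ventrally toothed
11	Rostrum minimal ventral teeth or notches	0;1-2;3-6
12	Rostrum maximal ventral teeth or notches	0;1-2;6-11
13	Minimal teeth or notches on carapace	0;1-5;6-10
14	Maximal teeth or notches on carapace	0;1-5;6-10
15	Postrostral dorsal carina beyond midlength	absent;present
16	Carapace antennal angle	blunt;acute
17	Acute pterygostomial tooth	absent;present
18	Dorsal organ under carapace	absent or inconspicuous;conspicuous
19	Dorsal organ extent	restricted to postorbital region;extended beyond postorbital region
20	Dorsal organ structure	nearly entire;four-lobed without pores;four-lobed with a pore
21	Pleura of 3rd abdominal segment	smooth;serrated
22	Telson long linear row of dorsolateral spines	absent;present
23	Telson long sinuous row of dorsolateral spines	absent;present
24	Telson strong spines on posterior margin	2-4;6 or more
25	Telson posterior margin	convex;concave
26	Telson posterior concave margin	shallow incision;nearly bilobed
27	Eyestalks partly fused	not fused partly;fused partly with mould seam
28	Eyestalks entirely fused	not fused entirely;fused entirely without mould seam
29	Eye anterior margin	entire;with conspicuous tubercle
30	Antenna II	not operculiform;operculiform
31	Maxilla II plumose bacteriophorous setae	absent;present
32	Maxilliped III epipod shape	subtriangular;strap-like
33	Maxilliped III epipod hook	not terminated in hook;terminated in hook
34	Maxilliped III merus	unarmed;with 1-2 distal spines
35	Pereopod I epipod	absent or rudimentary;strap-like
36	Pereopod I epipod hook	not terminated in hook;terminated in hook
37	Pereopod I grooming apparatus	absent or inconspicuous;conspicuous
38	Pereopod II epipod	absent or rudimentary;strap-like
39	Pereopod II epipod hook	not terminated in hook;terminated in hook
40	Pereopod II movable spines on ischium	absent;present
41	Pereopod III epipod	absent or rudimentary;strap-like
42	Pereopod III epipod hook	not terminated in hook;terminated in hook
43	Pereopod III strong movable spines on ischium	absent;present
44	Pereopod III proximal strong movable spines on merus	absent;present
45	Pereopod III distal movable spines on merus	absent;present
46	Pereopod III dactyl single row of accessory spinules	absent;present
47	Pereopod III dactyl two or more rows of accessory spinules	absent;present
48	Pereopod IV epipod	absent or rudimentary;strap-like
49	Pereopod IV epipod hook	not terminated in hook;terminated in hook
50	Pereopod IV strong movable spines on ischium	absent;present
51	Pereopod IV proximal strong movable spines on merus	absent;present
52	Pereopod IV distal movable spines on merus	absent;present
53	Pereopod IV dactyl single row of accessory spinules	absent;present
54	Pereopod IV dactyl two or more rows of accessory spinules	absent;present
55	Pereopod V strong movable spines on ischium	absent;present
56	Pereopod V dactyl single row of accessory spinules	absent;present
57	Pereopod V dactyl two or more rows of accessory spinules	absent;present
58	Pleopod II appendix interna	developed;much reduced
59	Pleopod III appendix interna	developed;much reduced
60	Pleopod IV appendix interna	developed;much reduced
61	Uropodal exopod single movable spine mesial to posterolateral tooth	absent;present
62	Uropodal exopod two movable spines mesial to posterolateral tooth	absent;present
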