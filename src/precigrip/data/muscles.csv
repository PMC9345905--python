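# Hand muscle parameters: 37 muscles, maximum force [N] and constant moment arms [mm].
# Sign convention: positive = flexion / adduction torque. Blank = muscle does not span the axis.
# Note: the FDP2 PIP arm is -8.5 mm, anomalous in sign for a deep flexor (all other FDP rows are
# positive at PIP); it is retained as tabulated in the source parameter set.
finger,no,name,abbreviation,f_max_N,cmc1_fe,cmc1_aa,mp1_fe,mp1_aa,ip1_fe,mp2_fe,mp2_aa,pip2_fe,dip2_fe,mp3_fe,mp3_aa,pip3_fe,dip3_fe,mp4_fe,mp4_aa,pip4_fe,dip4_fe,mp5_fe,mp5_aa,pip5_fe,dip5_fe
thumb,1,Flexor pollicis longus,FPL,2.7,14.3,0.2,13.6,-0.1,8.7,,,,,,,,,,,,,,,,
thumb,2,Extensor pollicis longus,EPL,1.3,-8.1,-9.5,-8.5,-4.4,-4.1,,,,,,,,,,,,,,,,
thumb,3,Abductor pollicis longus,ABPL,3.1,-7.1,10.5,0,0,0,,,,,,,,,,,,,,,,
thumb,4,Extensor pollicis brevis,EPB,0.8,-13,3.2,-8.6,3.2,0,,,,,,,,,,,,,,,,
thumb,5,Abductor pollicis brevis,ABPB,1.1,-3.9,16.5,2.6,16.5,0,,,,,,,,,,,,,,,,
thumb,6,Flexor pollicis brevis,FBP,1.3,13.4,10.5,8.8,10.5,0,,,,,,,,,,,,,,,,
thumb,7,Opponens pollicis,OP,1.9,12.9,4.8,0,4.8,0,,,,,,,,,,,,,,,,
thumb,8,Adductor pollicis transverse,APt,3,36.9,-20.6,9.7,-20.6,0,,,,,,,,,,,,,,,,
thumb,9,Adductor pollicis oblique,APo,3,27,-17,8.2,-17,0,,,,,,,,,,,,,,,,
index,10,Flexor digitorum superficialis 2,FDS2,2,,,,,,11.9,1.7,13.6,0,,,,,,,,,,,,
index,11,Flexor digitorum profundus 2,FDP2,2.7,,,,,,10.2,0.4,-8.5,4,,,,,,,,,,,,
index,12,Extensor digitorum communis 2,EDC2,1,,,,,,-9.4,0.7,0,-1.6,,,,,,,,,,,,
index,13,Extensor indicis,EI,1,,,,,,-9.4,0.7,-8.6,-1.6,,,,,,,,,,,,
index,14,1st lumbrical,1LU,0.2,,,,,,9.6,-9.9,2.6,-2,,,,,,,,,,,,
index,15,1st palmar interossei,1PI,1.3,,,,,,6.4,8.8,8.8,-2,,,,,,,,,,,,
index,16,1st dorsal interossei,1DI,3.2,,,,,,4.4,-9.6,0,0,,,,,,,,,,,,
middle,17,Flexor digitorum superficialis 3,FDS3,3.4,,,,,,,,,,11.5,0.6,5.3,0,,,,,,,,
middle,18,Flexor digitorum profundus 3,FDP3,3.4,,,,,,,,,,9.2,0.2,7.1,4.2,,,,,,,,
middle,19,Extensor digitorum communis 3,EDC3,1.9,,,,,,,,,,-9.3,-0.9,-3.3,-1.5,,,,,,,,
middle,20,2nd lumbrical,2LU,0.2,,,,,,,,,,10.5,8.2,-2.8,-1.9,,,,,,,,
middle,21,2nd dorsal interossei,2DI,2.5,,,,,,,,,,8,9.4,-1.1,-0.8,,,,,,,,
middle,22,3rd dorsal interossei,3DI,2,,,,,,,,,,3.4,-7.6,-2.6,-1.8,,,,,,,,
ring,23,Flexor digitorum superficialis 4,FDS4,2,,,,,,,,,,,,,,9.9,-1.2,5,0,,,,
ring,24,Flexor digitorum profundus 4,FDP4,3,,,,,,,,,,,,,,8.9,-0.8,6.2,4.1,,,,
ring,25,Extensor digitorum communis 4,EDC4,1.7,,,,,,,,,,,,,,-8.1,-0.5,-2.4,-1.2,,,,
ring,26,3rd lumbrical,3LU,0.1,,,,,,,,,,,,,,6.6,-7.5,-2,-1.5,,,,
ring,27,2nd palmar interossei,2PI,1.2,,,,,,,,,,,,,,3.1,-7.6,-2,-1.5,,,,
ring,28,4th dorsal interossei,4DI,1.7,,,,,,,,,,,,,,4.7,7.1,-1.2,-0.9,,,,
little,29,Flexor digitorum superficialis 5,FDS5,0.9,,,,,,,,,,,,,,,,,,8.6,3.2,4.7,0
little,30,Flexor digitorum profundus 5,FDP5,2.8,,,,,,,,,,,,,,,,,,8.5,4,5.9,3.2
little,31,Extensor digitorum communis 5,EDC5,0.9,,,,,,,,,,,,,,,,,,-4.9,0.9,-2.6,-1.3
little,32,Extensor digiti minimi,EDM,1,,,,,,,,,,,,,,,,,,-4.8,0.9,-2.6,-1.3
little,33,Abductor digiti minimi,ABDM,1.4,,,,,,,,,,,,,,,,,,4.7,-8,-2,-1.5
little,34,Flexor digiti minimi brevis,FDMB,0.4,,,,,,,,,,,,,,,,,,7.9,0,0,0
little,35,4th lumbrical,4LU,2,,,,,,,,,,,,,,,,,,6.3,7.2,-2.2,-1.7
little,36,3rd palmar interossei,3PI,1,,,,,,,,,,,,,,,,,,2.1,7.7,-2,-1.5
little,37,Opponens digiti minimi,ODM,2,,,,,,,,,,,,,,,,,,6,0,0,0
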