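wavelength_nm,eps_hbo2,eps_hb
440,84000.0,95000.0
442,78971.6,84604.2
444,74266.8,75474.9
446,69877.0,67552.7
448,65791.8,60757.5
450,62000.0,55000.0
452,58380.2,49812.8
454,54851.9,44875.5
456,51456.7,40285.6
458,48226.9,36103.0
460,45186.2,32357.4
462,42351.0,29055.0
464,39731.5,26186.0
466,37333.0,23730.2
468,35156.8,21661.9
470,33201.4,19954.4
472,31463.4,18582.8
474,29938.6,17526.5
476,28622.3,16771.5
478,27510.4,16312.6
480,26600.0,16156.0
482,25798.7,16238.2
484,25022.0,16468.9
486,24279.6,16826.1
488,23579.6,17288.8
490,22929.2,17835.4
492,22335.0,18441.8
494,21802.6,19081.0
496,21337.4,19721.7
498,20944.3,20328.5
500,20628.4,20862.0
502,20395.0,21323.1
504,20250.0,21749.0
506,20200.0,22153.2
508,20339.0,22550.5
510,20731.5,22956.7
512,21345.3,23389.0
514,22150.9,23865.8
516,23117.8,24406.9
518,24211.1,25034.5
520,25388.9,25773.0
522,26600.0,26807.9
524,28137.6,28278.2
526,30299.6,30141.5
528,33029.3,32347.1
530,36245.0,34825.7
532,39815.5,37479.3
534,43539.6,40173.9
536,47132.0,42735.9
538,50224.6,44954.2
540,52391.2,46592.0
542,53200.0,47869.4
544,52314.0,49137.2
546,50011.5,50343.1
548,46856.4,51430.1
550,43372.7,52337.6
552,39986.5,53003.1
554,37013.5,53364.2
556,34678.4,53347.5
558,33152.1,52855.0
560,32600.0,51935.7
562,33353.9,50665.1
564,35426.1,49121.2
566,38577.3,47380.8
568,42535.9,45515.9
570,46900.7,43592.0
572,51072.5,41666.6
574,54245.5,39788.9
576,55500.0,38000.0
578,53525.1,36047.8
580,48573.4,33764.0
582,42207.6,31299.5
584,35736.1,28784.4
586,30000.0,26323.2
588,23856.7,23994.4
590,17369.4,21852.3
592,11988.4,19931.0
594,8122.1,18248.7
596,5592.7,16812.5
598,4052.7,15622.8
600,3200.0,14677.0
602,2691.7,13915.7
604,2301.0,13261.1
606,1995.4,12687.3
608,1752.1,12172.3
610,1555.0,11697.5
612,1392.2,11247.0
614,1255.3,10807.1
616,1137.6,10365.9
618,1034.4,9913.8
620,942.0,9443.0
622,858.5,8950.2
624,783.8,8446.3
626,717.4,7944.3
628,658.8,7455.3
630,607.5,6987.9
632,562.9,6548.7
634,524.5,6142.4
636,491.8,5772.5
638,464.4,5440.9
640,442.0,5149.0
642,422.8,4885.2
644,405.3,4637.5
646,389.4,4406.1
648,375.0,4190.9
650,362.2,3991.8
652,350.8,3808.5
654,341.0,3640.7
656,332.5,3488.2
658,325.5,3350.4
660,320.0,3227.0
662,315.2,3116.8
664,310.7,3017.2
666,306.4,2926.4
668,302.5,2842.4
670,298.9,2763.9
672,295.9,2689.2
674,293.4,2617.3
676,291.6,2547.0
678,290.4,2477.2
680,290.0,2407.0
682,290.0,2336.8
684,290.0,2267.8
686,290.0,2200.4
688,290.0,2134.9
690,290.0,2071.5
692,290.0,2010.5
694,290.0,1952.1
696,290.0,1896.4
698,290.0,1843.7
700,290.0,1794.0
702,290.7,1744.4
704,292.7,1692.7
706,295.8,1640.2
708,300.1,1588.0
710,305.3,1537.1
712,311.5,1488.3
714,318.4,1442.3
716,326.1,1399.8
718,334.4,1361.5
720,343.3,1327.7
722,352.5,1299.0
724,361.9,1275.7
726,371.4,1258.5
728,380.9,1247.7
730,390.0,1244.0
732,399.4,1248.7
734,409.7,1262.1
736,420.9,1283.0
738,432.9,1310.5
740,445.6,1343.5
742,458.9,1381.0
744,472.8,1421.8
746,487.1,1464.6
748,501.7,1507.9
750,516.4,1550.0
752,531.1,1589.1
754,545.7,1623.1
756,559.8,1650.0
758,573.3,1667.7
760,586.0,1674.0
762,598.2,1668.5
764,610.3,1653.0
766,622.4,1628.8
768,634.5,1597.6
770,646.5,1561.0
772,658.4,1520.3
774,670.2,1477.1
776,682.0,1432.7
778,693.7,1388.3
780,705.4,1345.0
782,716.9,1291.3
784,728.3,1220.8
786,739.7,1141.7
788,750.9,1060.7
790,762.0,983.4
792,773.0,913.8
794,784.0,855.0
796,794.8,808.9
798,805.4,777.3
800,816.0,762.0
802,826.5,755.8
804,837.1,750.0
806,847.7,744.4
808,858.3,739.3
810,868.9,734.4
812,879.5,729.8
814,890.1,725.5
816,900.6,721.5
818,911.1,717.8
820,921.5,714.4
822,931.9,711.2
824,942.1,708.3
826,952.2,705.6
828,962.2,703.2
830,972.0,701.0
832,981.7,699.0
834,991.2,697.3
836,1000.5,695.8
838,1009.5,694.5
840,1018.3,693.4
842,1026.9,692.5
844,1035.1,691.9
846,1043.1,691.4
848,1050.7,691.1
850,1058.0,691.0
852,1065.1,691.2
854,1072.4,691.6
856,1079.6,692.4
858,1086.8,693.3
860,1094.1,694.6
862,1101.3,696.0
864,1108.4,697.6
866,1115.5,699.3
868,1122.5,701.2
870,1129.3,703.1
872,1136.0,705.2
874,1142.5,707.2
876,1148.8,709.3
878,1154.8,711.4
880,1160.6,713.5
882,1166.1,715.5
884,1171.3,717.4
886,1176.1,719.2
888,1180.6,720.8
890,1184.7,722.3
892,1188.3,723.5
894,1191.5,724.6
896,1194.2,725.3
898,1196.4,725.8
900,1198.0,726.0
902,1199.3,725.9
904,1200.7,725.5
906,1201.9,725.0
908,1203.2,724.2
910,1204.3,723.3
912,1205.5,722.2
914,1206.5,720.9
916,1207.6,719.4
918,1208.5,717.8
920,1209.4,716.0
922,1210.2,714.2
924,1211.0,712.2
926,1211.7,710.0
928,1212.3,707.8
930,1212.8,705.5
932,1213.2,703.1
934,1213.6,700.7
936,1213.8,698.2
938,1213.9,695.6
940,1214.0,693.0
942,1213.9,689.9
944,1213.7,685.8
946,1213.3,680.8
948,1212.9,675.0
950,1212.2,668.4
952,1211.5,661.2
954,1210.6,653.4
956,1209.6,645.2
958,1208.5,636.5
960,1207.3,627.5
962,1206.1,618.2
964,1204.7,608.8
966,1203.2,599.2
968,1201.6,589.5
970,1200.0,579.8
972,1197.4,570.2
974,1193.3,560.7
976,1187.6,551.4
978,1180.8,542.2
980,1172.9,533.3
982,1164.3,524.6
984,1155.0,516.3
986,1145.2,508.4
988,1135.2,500.8
990,1125.2,493.6
992,1115.3,486.9
994,1105.6,480.7
996,1096.4,474.9
998,1087.8,469.7
1000,1080.0,465.0
1002,1072.6,460.7
1004,1065.4,456.6
1006,1058.2,452.7
1008,1051.1,449.0
1010,1044.1,445.5
1012,1037.1,442.1
1014,1030.2,438.9
1016,1023.4,435.8
1018,1016.7,432.8
1020,1010.0,430.0
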